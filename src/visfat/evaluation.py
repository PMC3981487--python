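"""Validation statistics for calculated visceral fat volumes.

Ships the 24-subject reference table (12 female, 12 male; three subjects per
BMI category under 20 / 20-25 / 25-30 / over 30 and sex) of anthropometrics,
manually segmented "true" visceral fat volumes and automatically calculated
volumes, and computes the statistics used to validate the method: Pearson
correlation of true vs calculated volume, per-subject error ratios
(|calculated - true| / true), their median, and correlations of the three
substitute adiposity indices (BMI, waist circumference, 2D visceral fat
area at the umbilicus) with both volumes.

Note on BMI: the table's printed BMI column is rounded to one decimal; the
substitute-index correlations use BMI recomputed as weight / height^2 at
full precision, which is what reproduces the reference correlation values.
The same statistics can be computed for any user-supplied set of records,
e.g. phantom runs.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SubjectRecord",
    "table1_records",
    "records_frame",
    "pearson",
    "error_ratio",
    "median_error_ratio",
    "substitute_index_correlations",
    "dice_coefficient",
    "evaluation_report",
]

_SEXES = ("female", "male")


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: anthropometrics plus true and calculated visceral fat volume."""

    sex: str
    height_m: float
    weight_kg: float
    bmi_kg_m2: float
    waist_circumference_cm: float
    visceral_fat_area_cm2: float
    true_volume_cm3: float
    calculated_volume_cm3: float

    def __post_init__(self) -> None:
        if self.sex not in _SEXES:
            raise ValueError(f"sex must be one of {_SEXES}, got {self.sex!r}")
        vals = (self.height_m, self.weight_kg, self.bmi_kg_m2,
                self.waist_circumference_cm, self.visceral_fat_area_cm2,
                self.true_volume_cm3, self.calculated_volume_cm3)
        if any(v <= 0 for v in vals):
            raise ValueError(f"all subject values must be positive: {self}")
        if abs(self.bmi_kg_m2 - self.weight_kg / self.height_m**2) > 0.15:
            raise ValueError(f"BMI inconsistent with height/weight: {self}")

    @property
    def bmi_exact(self) -> float:
        """BMI recomputed from height and weight (the printed column is rounded)."""
        return self.weight_kg / self.height_m**2

    @property
    def absolute_error_cm3(self) -> float:
        return abs(self.calculated_volume_cm3 - self.true_volume_cm3)


def table1_records() -> list[SubjectRecord]:
    """The embedded 24-subject reference table."""
    src = importlib.resources.files("visfat.data").joinpath("subjects.csv")
    with importlib.resources.as_file(src) as p:
        df = pd.read_csv(p)
    return [SubjectRecord(**row) for row in df.to_dict(orient="records")]


def records_frame(records: Iterable[SubjectRecord]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in records])
    df["bmi_exact"] = df.weight_kg / df.height_m**2
    df["absolute_error_cm3"] = (df.calculated_volume_cm3 - df.true_volume_cm3).abs()
    return df


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson product-moment correlation of two equal-length lists."""
    from scipy.stats import pearsonr

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length 1D samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(pearsonr(x, y).statistic)


def error_ratio(true_cm3: float, calculated_cm3: float) -> float:
    """Relative volume error |calculated - true| / true, in percent."""
    if true_cm3 <= 0:
        raise ValueError(f"true volume must be positive, got {true_cm3}")
    return abs(calculated_cm3 - true_cm3) / true_cm3 * 100.0


def median_error_ratio(records: Sequence[SubjectRecord]) -> float:
    """Median per-subject error ratio in percent (mean of middle two for even n)."""
    if not records:
        raise ValueError("no records")
    return float(np.median([
        error_ratio(r.true_volume_cm3, r.calculated_volume_cm3) for r in records
    ]))


def substitute_index_correlations(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Correlations of BMI / WC / visceral fat area with true and calculated volume.

    Returns a DataFrame indexed by (sex, index) with columns ``true`` and
    ``calculated``; each sex group needs at least 3 records.
    """
    df = records_frame(records)
    rows = {}
    for sex, g in df.groupby("sex"):
        for label, col in (
            ("BMI", "bmi_exact"),
            ("Waist circumference", "waist_circumference_cm"),
            ("Visceral fat area", "visceral_fat_area_cm2"),
        ):
            rows[(sex, label)] = {
                "true": pearson(g[col], g.true_volume_cm3),
                "calculated": pearson(g[col], g.calculated_volume_cm3),
            }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index = pd.MultiIndex.from_tuples(out.index, names=["sex", "index"])
    return out


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) of two binary masks (1.0 if both empty)."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def evaluation_report(records: Sequence[SubjectRecord] | None = None) -> dict:
    """All validation statistics as one nested dict (defaults to the embedded table)."""
    if records is None:
        records = table1_records()
    by_sex = {s: [r for r in records if r.sex == s] for s in _SEXES}
    report: dict = {"n": len(records)}
    for sex, recs in by_sex.items():
        if not recs:
            continue
        report[sex] = {
            "n": len(recs),
            "pearson_true_vs_calculated": pearson(
                [r.true_volume_cm3 for r in recs],
                [r.calculated_volume_cm3 for r in recs],
            ),
            "median_error_ratio_pct": median_error_ratio(recs),
        }
    corr = substitute_index_correlations(records)
    report["substitute_index_correlations"] = {
        f"{sex}/{idx}": {"true": row["true"], "calculated": row["calculated"]}
        for (sex, idx), row in corr.iterrows()
    }
    return report
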