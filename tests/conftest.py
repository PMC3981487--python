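import numpy as np
import pytest

import visfat
from visfat.evaluation import dice_coefficient


@pytest.fixture(scope="session")
def phantom_suite():
    """The four default phantoms (sigma = 3 HU), generated once per session."""
    out = []
    for spec in visfat.default_specs(0):
        vol, truth = visfat.generate_phantom(spec)
        out.append((spec, vol, truth))
    return out


@pytest.fixture(scope="session")
def pipeline_runs(phantom_suite):
    """Full pipeline results on each default phantom (no rescale: phantoms are
    generated at the working resolution)."""
    cfg = visfat.PipelineConfig(rescale=False)
    runs = []
    for spec, vol, truth in phantom_suite:
        res = visfat.run(vol, cfg)
        runs.append((spec, truth, res))
    return runs


@pytest.fixture(scope="session")
def recovery_table(pipeline_runs):
    """Per-phantom visceral-volume error (%) and per-tissue Dice overlaps."""
    rows = []
    for spec, truth, res in pipeline_runs:
        gt = truth.visceral_volume_cm3
        calc = res.fat.visceral_volume_cm3
        rows.append({
            "name": spec.name,
            "gt_cm3": gt,
            "calc_cm3": calc,
            "error_pct": abs(calc - gt) / gt * 100.0,
            "dice": {
                n: dice_coefficient(
                    getattr(res.tissues, n).voxels, getattr(truth.tissues, n).voxels
                )
                for n in ("fat", "muscle", "bone", "air")
            },
        })
    return rows


def random_mask(seed: int, shape=(8, 8, 8), p: float = 0.35) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.random(shape) < p
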