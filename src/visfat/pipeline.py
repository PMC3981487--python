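"""End-to-end visceral fat volume calculation.

Stage order: half-resolution rescale -> trunk extraction -> bone / muscle /
air / fat segmentation -> superior (lung base) and inferior (pubic
symphysis) measurement bounds -> visceral-region delineation -> per-voxel
fat classification and volume calculation.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

from . import axial_range as ar
from . import tissue, visceral, volume

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Parameters of a segmentation run; defaults are the method's standard values."""

    thresholds: tissue.Thresholds = field(default_factory=tissue.Thresholds)
    visceral_radius: float = 20.0   #: visceral closing kernel, voxels
    rescale: bool = True            #: halve the input first (turn off for data
    #: already at the ~2 mm working resolution)


@dataclass
class PipelineResult:
    """Everything a run produces, for reporting and inspection."""

    fat: visceral.FatResult
    tissues: tissue.TissueMaps
    axial_range: ar.AxialRange
    working_volume: volume.CTVolume
    stage_voxels: dict[str, int]
    stage_seconds: dict[str, float]

    def report(self) -> dict:
        return {
            **self.fat.to_dict(),
            "inferior_z": self.axial_range.inferior_z,
            "stage_voxels": self.stage_voxels,
        }


def run(vol: volume.CTVolume, config: PipelineConfig = PipelineConfig()) -> PipelineResult:
    """Run the full calculation on a CT volume in HU."""
    counts: dict[str, int] = {}
    seconds: dict[str, float] = {}

    def timed(name, fn, *args, **kw):
        t0 = time.perf_counter()
        out = fn(*args, **kw)
        seconds[name] = time.perf_counter() - t0
        if hasattr(out, "count"):
            counts[name] = out.count()
        log.info("stage %-16s %6.2fs  %s", name, seconds[name],
                 f"{counts[name]} voxels" if name in counts else "")
        return out

    th = config.thresholds
    work = timed("rescale", volume.rescale_halved, vol) if config.rescale else vol
    trunk = timed("trunk", tissue.extract_trunk, work, th)
    bone = timed("bone", tissue.segment_bone, work, trunk, th)
    muscle = timed("muscle", tissue.segment_muscle, work, trunk, bone, th)
    air = timed("air", tissue.segment_air, work, trunk, th)
    fat = timed("fat", tissue.segment_fat, work, trunk, bone, muscle, air, th)
    maps = tissue.TissueMaps(trunk=trunk, bone=bone, muscle=muscle, air=air, fat=fat)
    maps.validate()

    left, right = ar.detect_lungs(air)
    surface = timed("lung_surface", ar.fit_superior_surface, left, right)
    inferior_z = ar.detect_pubic_symphysis(bone)
    rng = ar.make_axial_range(surface, inferior_z, nz=work.shape[2])

    region = timed("visceral_region", visceral.delineate_visceral,
                   bone, muscle, air, config.visceral_radius)
    result = visceral.classify_fat(fat, region, rng)
    log.info("visceral %.1f cm^3, subcutaneous %.1f cm^3",
             result.visceral_volume_cm3, result.subcutaneous_volume_cm3)
    return PipelineResult(
        fat=result,
        tissues=maps,
        axial_range=rng,
        working_volume=work,
        stage_voxels=counts,
        stage_seconds=seconds,
    )
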