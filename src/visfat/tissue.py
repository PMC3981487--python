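"""Trunk extraction and bone/muscle/air/fat segmentation.

All operations run on the half-resolution working volume and use HU
thresholds compared exactly as written (``>=`` for lower bounds, ``<`` for
strict upper bounds; the adipose window is inclusive on both ends).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import morphology as morph
from .morphology import spherical_kernel
from .volume import CTVolume, LabelMask

__all__ = [
    "Thresholds",
    "TissueMaps",
    "extract_trunk",
    "segment_bone",
    "segment_muscle",
    "segment_air",
    "segment_fat",
    "segment_tissues",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Thresholds:
    """HU thresholds and morphology parameters of the segmentation stages.

    The defaults are the method's standard operating point; every field can
    be overridden (e.g. from the CLI).
    """

    trunk_hu: float = -400.0     #: body trunk lower bound
    bone_hu: float = 200.0       #: bone seed lower bound
    muscle_hu: float = 30.0      #: muscle lower bound
    air_hu: float = -220.0       #: air strict upper bound
    fat_low: float = -190.0      #: adipose window, inclusive
    fat_high: float = -30.0      #: adipose window, inclusive
    muscle_min_depth: float = 5.0    #: min distance from body surface, voxels
    muscle_min_volume: int = 20      #: min component volume, voxels (~190 mm^3)
    seed_kernel_r: float = 1.5       #: trunk closing / bone seed kernel radius
    fat_close_r: float = 1.0         #: exclusion-region closing radius

    def __post_init__(self) -> None:
        if not (self.trunk_hu < self.air_hu < self.fat_low < self.fat_high
                < self.muscle_hu < self.bone_hu):
            raise ValueError(
                "thresholds must satisfy trunk < air < fat_low < fat_high "
                f"< muscle < bone, got {self}"
            )


@dataclass
class TissueMaps:
    """Bundle of the per-tissue masks, all subsets of the trunk."""

    trunk: LabelMask
    bone: LabelMask
    muscle: LabelMask
    air: LabelMask
    fat: LabelMask

    def validate(self) -> None:
        t = self.trunk.voxels
        for name in ("bone", "muscle", "air", "fat"):
            m = getattr(self, name).voxels
            if (m & ~t).any():
                raise ValueError(f"{name} mask escapes the trunk")
        others = self.bone.voxels | self.muscle.voxels | self.air.voxels
        if (self.fat.voxels & others).any():
            raise ValueError("fat mask overlaps bone/muscle/air")


def extract_trunk(vol: CTVolume, th: Thresholds = Thresholds()) -> LabelMask:
    """Extract the body trunk, rejecting the scanner couch and outside air.

    Per axial slice the largest component at or above ``trunk_hu`` is kept
    (the couch is a smaller, detached component) and sub-threshold 2D
    components not touching the slice border (lungs, bowel gas) are added.
    The stacked result is closed in 3D with the 1.5-voxel spherical kernel.
    """
    high = vol.voxels >= th.trunk_hu
    if not high.any():
        raise ValueError("no body found: no voxel at or above the trunk threshold")
    s2 = ndimage.generate_binary_structure(2, 1)
    out = np.zeros(vol.shape, dtype=bool)
    for z in range(vol.shape[2]):
        h = high[:, :, z]
        if not h.any():
            continue
        lab, n = ndimage.label(h, structure=s2)
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        sel = lab == sizes.argmax()
        # sub-threshold pockets enclosed in the slice
        low_lab, _ = ndimage.label(~h, structure=s2)
        border = np.unique(
            np.concatenate([low_lab[0, :], low_lab[-1, :], low_lab[:, 0], low_lab[:, -1]])
        )
        interior = (low_lab > 0) & ~np.isin(low_lab, border)
        out[:, :, z] = sel | interior
    mask = LabelMask(out, vol.spacing)
    return morph.close(mask, spherical_kernel(th.seed_kernel_r))


def segment_bone(vol: CTVolume, trunk: LabelMask, th: Thresholds = Thresholds()) -> LabelMask:
    """Segment the skeleton including low-HU medullary cavities.

    Threshold at ``bone_hu``, dilate (r = 1.5), keep the largest component as
    the bone seed, fill enclosed blanks (3D background components not
    touching the volume edge), then erode (r = 1.5).
    """
    cand = LabelMask((vol.voxels >= th.bone_hu) & trunk.voxels, vol.spacing)
    if not cand.voxels.any():
        log.warning("no voxel at or above %.0f HU: returning an empty bone mask", th.bone_hu)
        return cand
    k = spherical_kernel(th.seed_kernel_r)
    seed = morph.connected_components(morph.dilate(cand, k))[0]
    filled = morph.fill_holes(seed, scope="volume3d")
    eroded = morph.erode(filled, k)
    # closing can pick up voxels at concavities just outside the body
    return LabelMask(eroded.voxels & trunk.voxels, vol.spacing)


def segment_muscle(
    vol: CTVolume, trunk: LabelMask, bone: LabelMask, th: Thresholds = Thresholds()
) -> LabelMask:
    """Segment muscle by four component selection rules.

    A candidate component (>= ``muscle_hu`` inside the trunk) is kept iff it
    contains no bone voxel and has at least ``muscle_min_volume`` voxels;
    within kept components, voxels closer than ``muscle_min_depth`` to the
    body surface are trimmed (the depth rule is applied per voxel so the
    abdominal wall survives where its deep portion qualifies).
    """
    cand = (vol.voxels >= th.muscle_hu) & trunk.voxels
    lab, n = ndimage.label(cand, structure=ndimage.generate_binary_structure(3, 1))
    if n == 0:
        return LabelMask(cand, vol.spacing)
    sizes = np.bincount(lab.ravel())
    keep = sizes >= th.muscle_min_volume
    keep[0] = False
    bone_labels = np.unique(lab[bone.voxels & cand])
    keep[bone_labels[bone_labels > 0]] = False
    depth = morph.distance_from_boundary(trunk)
    out = keep[lab] & (depth >= th.muscle_min_depth)
    return LabelMask(out, vol.spacing)


def segment_air(vol: CTVolume, trunk: LabelMask, th: Thresholds = Thresholds()) -> LabelMask:
    """Air inside the trunk: every component below ``air_hu`` (lungs, bowel gas)."""
    return LabelMask((vol.voxels < th.air_hu) & trunk.voxels, vol.spacing)


def segment_fat(
    vol: CTVolume,
    trunk: LabelMask,
    bone: LabelMask,
    muscle: LabelMask,
    air: LabelMask,
    th: Thresholds = Thresholds(),
) -> LabelMask:
    """Adipose tissue: the HU window inside the trunk, minus the closed union
    of bone, muscle and air.

    The union is closed with a 1.0-voxel spherical kernel first, which seals
    one-voxel fat-valued cracks between excluded tissues (intermuscular
    partial-volume voxels, air-boundary voxels, noise).
    """
    union = LabelMask(bone.voxels | muscle.voxels | air.voxels, vol.spacing)
    exclusion = morph.close(union, spherical_kernel(th.fat_close_r))
    window = (vol.voxels >= th.fat_low) & (vol.voxels <= th.fat_high)
    return LabelMask(window & trunk.voxels & ~exclusion.voxels, vol.spacing)


def segment_tissues(vol: CTVolume, th: Thresholds = Thresholds()) -> TissueMaps:
    """Run trunk extraction and all four tissue stages in order."""
    trunk = extract_trunk(vol, th)
    bone = segment_bone(vol, trunk, th)
    muscle = segment_muscle(vol, trunk, bone, th)
    air = segment_air(vol, trunk, th)
    fat = segment_fat(vol, trunk, bone, muscle, air, th)
    maps = TissueMaps(trunk=trunk, bone=bone, muscle=muscle, air=air, fat=fat)
    maps.validate()
    return maps
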