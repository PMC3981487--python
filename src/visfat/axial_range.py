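"""Superior/inferior bounds of the fat measurement range.

The cranial bound is the lung-base surface (a diaphragm proxy) fitted by
thin-plate-spline radial basis interpolation to the most caudal lung voxel
of every column intersecting either lung.  The caudal bound is the axial
plane through the cranial edge of the pubic symphysis, found as the
anteriormost bony voxel in a 5-column (9.8 mm) midsagittal slab.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import morphology as morph
from .volume import LabelMask

__all__ = [
    "AxialRange",
    "detect_lungs",
    "fit_superior_surface",
    "detect_pubic_symphysis",
    "make_axial_range",
    "apply_range",
]


@dataclass
class AxialRange:
    """Measurement bounds: per-column superior z surface and an inferior plane.

    ``superior_surface[x, y]`` is the (real-valued) z index at and below
    which measurement is allowed; ``inferior_z`` is the inclusive caudal
    plane.  The surface is clamped into ``[0, inferior_z]`` at construction
    so the bound invariant holds for every column.
    """

    superior_surface: np.ndarray
    inferior_z: int

    def __post_init__(self) -> None:
        self.superior_surface = np.asarray(self.superior_surface, dtype=np.float64)
        if self.superior_surface.ndim != 2:
            raise ValueError("superior_surface must be a 2D (x, y) map")
        self.inferior_z = int(self.inferior_z)
        if (self.superior_surface > self.inferior_z).any():
            raise ValueError("superior surface lies below the inferior plane")


def detect_lungs(air: LabelMask) -> tuple[LabelMask, LabelMask]:
    """The two largest air components, returned as (left, right).

    Left/right is assigned by centroid x (x increases toward the patient's
    left); equally sized lungs are still ordered deterministically.
    """
    comps = morph.connected_components(air)
    if len(comps) < 2:
        raise ValueError(f"lungs not found: {len(comps)} air component(s)")
    a, b = comps[0], comps[1]
    ca = np.argwhere(a.voxels)[:, 0].mean()
    cb = np.argwhere(b.voxels)[:, 0].mean()
    left, right = (a, b) if ca >= cb else (b, a)
    return left, right


def _caudal_samples(lung: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    footprint = lung.any(axis=2)
    nz = lung.shape[2]
    zmax = np.where(lung, np.arange(nz)[None, None, :], -1).max(axis=2)
    cols = np.argwhere(footprint)
    return cols, zmax[footprint]


def fit_superior_surface(
    left_lung: LabelMask, right_lung: LabelMask, max_samples: int = 2000
) -> np.ndarray:
    """Thin-plate-spline surface through the caudal lung planes.

    For every (x, y) column intersecting either lung the most caudal lung
    voxel is a sample; the spline interpolates the samples exactly
    (smoothing 0) and is evaluated over the full slice footprint.  If there
    are more than ``max_samples`` samples, every 3rd column is used.
    """
    from scipy.interpolate import RBFInterpolator

    union = left_lung.voxels | right_lung.voxels
    if not left_lung.voxels.any() or not right_lung.voxels.any():
        raise ValueError("both lungs must be nonempty")
    pts, vals = _caudal_samples(union)
    if len(pts) > max_samples:
        pts, vals = pts[::3], vals[::3]
    if len(pts) < 3 or np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 2:
        raise ValueError("need >= 3 non-collinear lung-base samples")
    rbf = RBFInterpolator(pts.astype(float), vals.astype(float),
                          kernel="thin_plate_spline", smoothing=0.0)
    nx, ny = union.shape[:2]
    gx, gy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    grid = np.stack([gx.ravel(), gy.ravel()], axis=1).astype(float)
    return rbf(grid).reshape(nx, ny)


def detect_pubic_symphysis(bone: LabelMask) -> int:
    """z index of the plane through the cranial edge of the pubic symphysis.

    Searches the anteriormost bone voxel (maximal y) in a 5-column
    midsagittal slab, restricted to the caudal half of the volume so ribs or
    sternum cannot win in whole-body data; ties on y are broken toward the
    most cranial z.
    """
    nx, ny, nz = bone.shape
    cx = nx // 2
    slab = bone.voxels[max(cx - 2, 0): cx + 3, :, :]
    z0 = nz // 2
    sub = slab[:, :, z0:]
    if not sub.any():
        raise ValueError("pubic symphysis not found: no bone in the midsagittal slab")
    idx = np.argwhere(sub)
    ymax = idx[:, 1].max()
    z = z0 + int(idx[idx[:, 1] == ymax][:, 2].min())
    if z < (2 * nz) // 3:
        warnings.warn(
            f"anteriormost bone at z={z} is not in the caudal third; "
            "the pubic symphysis may have been missed",
            stacklevel=2,
        )
    return z


def make_axial_range(superior_surface: np.ndarray, inferior_z: int,
                     nz: int | None = None) -> AxialRange:
    """Clamp the fitted surface into ``[0, inferior_z]`` and build the range."""
    if nz is not None and not (0 <= inferior_z < nz):
        raise ValueError(f"inferior_z={inferior_z} outside the z extent [0, {nz})")
    surf = np.clip(np.asarray(superior_surface, float), 0.0, float(inferior_z))
    return AxialRange(surf, inferior_z)


def apply_range(mask: LabelMask, rng: AxialRange) -> LabelMask:
    """Keep voxels with ``superior_surface(x, y) <= z <= inferior_z`` (both inclusive)."""
    nx, ny, nz = mask.shape
    if rng.superior_surface.shape != (nx, ny):
        raise ValueError("surface footprint does not match the mask grid")
    z = np.arange(nz)[None, None, :]
    allowed = (z >= rng.superior_surface[:, :, None]) & (z <= rng.inferior_z)
    return mask.like(mask.voxels & allowed)
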