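"""CT volume data model, file I/O and half-resolution rescaling.

Axis convention used throughout the package
-------------------------------------------
Voxel arrays are indexed ``[x, y, z]`` with

* ``x`` increasing toward the patient's **left**,
* ``y`` increasing toward **anterior**,
* ``z`` increasing toward **inferior** (index 0 is the most superior slice).

``spacing`` is the physical voxel edge length ``(sx, sy, sz)`` in mm.
Voxel values are Hounsfield units (HU) stored as floating point after the
DICOM rescale slope/intercept has been applied.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "CTVolume",
    "LabelMask",
    "read_dicom_series",
    "read_volume",
    "write_volume",
    "write_mask",
    "rescale_halved",
]

#: ITK direction cosines (row-major) of our in-memory convention: index axes
#: point Left, Anterior, Inferior in the LPS physical frame.
_LAI_DIRECTION = (1.0, 0.0, 0.0, 0.0, -1.0, 0.0, 0.0, 0.0, -1.0)

_VOLUME_SUFFIXES = (".nii", ".nii.gz", ".mha", ".mhd")


@dataclass
class CTVolume:
    """A 3D grid of Hounsfield units with isotropic-in-plane voxel spacing.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        HU values, finite floats.
    spacing : tuple of float
        Voxel edge lengths ``(sx, sy, sz)`` in mm, all strictly positive.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.voxels.ndim}")
        if min(self.voxels.shape) < 2:
            raise ValueError(f"each axis needs >= 2 voxels, got shape {self.voxels.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive lengths, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("HU values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz


@dataclass
class LabelMask:
    """A binary mask aligned to a :class:`CTVolume` grid."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.dtype != bool:
            if not np.isin(v, (0, 1)).all():
                raise ValueError("mask values must be exactly {0, 1}")
            v = v.astype(bool)
        if v.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={v.ndim}")
        self.voxels = v
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def count(self) -> int:
        return int(self.voxels.sum())

    def like(self, voxels: np.ndarray) -> "LabelMask":
        """A new mask on the same grid."""
        return LabelMask(voxels, self.spacing)


def _require(ds, attr: str, path) -> object:
    if not hasattr(ds, attr) or getattr(ds, attr) is None:
        raise ValueError(f"DICOM file {path} is missing required attribute {attr}")
    return getattr(ds, attr)


def read_dicom_series(directory: os.PathLike | str) -> CTVolume:
    """Read a directory of single-frame axial CT slices as one volume.

    Slices are sorted by physical z position and stacked superior-first;
    rescale slope/intercept is applied so voxels are in HU.  Only pure axial
    orientations (row -> +y DICOM, column -> +x DICOM) are supported.

    Raises
    ------
    ValueError
        On fewer than two slices, mixed series UIDs, missing spacing or
        position metadata, non-axial orientation, or slice gaps that deviate
        from uniform by more than 1 %.
    """
    import pydicom

    directory = Path(directory)
    paths = sorted(p for p in directory.iterdir() if p.is_file())
    slices = []
    for p in paths:
        try:
            ds = pydicom.dcmread(p)
        except Exception:
            continue  # skip non-DICOM clutter (DICOMDIR, reports, ...)
        if getattr(ds, "pixel_array", None) is not None:
            slices.append((p, ds))
    if len(slices) < 2:
        raise ValueError(f"need >= 2 DICOM slices in {directory}, found {len(slices)}")

    uids = {str(_require(ds, "SeriesInstanceUID", p)) for p, ds in slices}
    if len(uids) != 1:
        raise ValueError(f"mixed SeriesInstanceUID values in {directory}: {sorted(uids)}")

    first = slices[0][1]
    orient = np.asarray(_require(first, "ImageOrientationPatient", slices[0][0]), float)
    if not np.allclose(orient, [1, 0, 0, 0, 1, 0], atol=1e-3):
        raise ValueError(f"unsupported (non-axial) ImageOrientationPatient {orient.tolist()}")

    px = _require(first, "PixelSpacing", slices[0][0])
    row_mm, col_mm = float(px[0]), float(px[1])

    # DICOM LPS: superior is +z, so superior-first means descending position z.
    keyed = []
    for p, ds in slices:
        pos = _require(ds, "ImagePositionPatient", p)
        keyed.append((float(pos[2]), p, ds))
    keyed.sort(key=lambda t: -t[0])

    zs = np.array([z for z, _, _ in keyed])
    gaps = np.abs(np.diff(zs))
    if gaps.min() <= 0:
        raise ValueError("duplicate slice positions in series")
    if (gaps.max() - gaps.min()) / gaps.mean() > 0.01:
        raise ValueError(
            f"non-uniform slice gaps beyond 1% tolerance: {sorted(set(np.round(gaps, 4)))}"
        )
    slice_mm = float(gaps.mean())

    planes = []
    for _, p, ds in keyed:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        inter = float(getattr(ds, "RescaleIntercept", 0.0))
        arr = ds.pixel_array.astype(np.float64) * slope + inter
        # rows run posterior (+y DICOM) -> flip so our y increases anterior;
        # columns run left (+x DICOM) already.
        planes.append(arr.T[:, ::-1])
    vox = np.stack(planes, axis=2)
    return CTVolume(vox, (col_mm, row_mm, slice_mm))


def _to_convention(img):
    """Reorient a SimpleITK image so index axes point Left/Anterior/Inferior."""
    import SimpleITK as sitk

    return sitk.DICOMOrient(img, "LAI")


def read_volume(path: os.PathLike | str) -> CTVolume:
    """Read a NIfTI (``.nii``/``.nii.gz``) or MetaImage (``.mha``/``.mhd``) volume.

    The voxel grid is reordered to the package convention (x left, y anterior,
    z inferior) using the file's orientation metadata.
    """
    import SimpleITK as sitk

    path = Path(path)
    name = path.name.lower()
    if not name.endswith(_VOLUME_SUFFIXES):
        raise ValueError(f"unknown volume extension for {path}; expected one of {_VOLUME_SUFFIXES}")
    if not path.exists():
        raise FileNotFoundError(path)
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise ValueError(f"expected 3D data, got {img.GetDimension()}D in {path}")
    img = _to_convention(img)
    arr = sitk.GetArrayFromImage(img)  # [z, y, x]
    vox = np.ascontiguousarray(arr.transpose(2, 1, 0)).astype(np.float64)
    return CTVolume(vox, tuple(img.GetSpacing()))


def _write(voxels: np.ndarray, spacing, path) -> None:
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(np.ascontiguousarray(voxels.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetDirection(_LAI_DIRECTION)
    path = Path(path)
    if not path.parent.is_dir():
        raise ValueError(f"output directory does not exist: {path.parent}")
    sitk.WriteImage(img, str(path))


def write_volume(vol: CTVolume, path: os.PathLike | str) -> None:
    """Write a volume readable back by :func:`read_volume` (round-trip exact)."""
    _write(vol.voxels, vol.spacing, path)


def write_mask(mask: LabelMask, path: os.PathLike | str) -> None:
    """Write a mask with foreground 1 / background 0, readable by :func:`read_volume`."""
    _write(mask.voxels.astype(np.uint8), mask.spacing, path)


def rescale_halved(vol: CTVolume) -> CTVolume:
    """Downsample to half resolution by 2x2x2 block averaging.

    Each output axis has ``floor(n/2)`` voxels and twice the input spacing
    (e.g. 0.98 x 0.98 x 1.25 mm -> 1.96 x 1.96 x 2.5 mm); odd trailing voxels
    are dropped.  Block averaging preserves mean HU so that downstream
    threshold steps stay stable.
    """
    nx, ny, nz = vol.shape
    if min(nx, ny, nz) < 2:
        raise ValueError(f"cannot halve a volume with shape {vol.shape}")
    hx, hy, hz = nx // 2, ny // 2, nz // 2
    v = vol.voxels[: 2 * hx, : 2 * hy, : 2 * hz]
    out = v.reshape(hx, 2, hy, 2, hz, 2).mean(axis=(1, 3, 5))
    return CTVolume(out, tuple(2.0 * s for s in vol.spacing))
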