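"""Volume model, file round trips, DICOM series assembly, and halving."""

import numpy as np
import pytest

from visfat.volume import (CTVolume, LabelMask, read_dicom_series, read_volume,
                           rescale_halved, write_mask, write_volume)


def test_ctvolume_invariants():
    with pytest.raises(ValueError):
        CTVolume(np.zeros((4, 4)), (1, 1, 1))  # 2D
    with pytest.raises(ValueError):
        CTVolume(np.zeros((4, 4, 1)), (1, 1, 1))  # too short an axis
    with pytest.raises(ValueError):
        CTVolume(np.zeros((4, 4, 4)), (1, -1, 1))  # nonpositive spacing
    bad = np.zeros((4, 4, 4))
    bad[0, 0, 0] = np.nan
    with pytest.raises(ValueError):
        CTVolume(bad, (1, 1, 1))


def test_labelmask_requires_binary():
    with pytest.raises(ValueError):
        LabelMask(np.full((3, 3, 3), 2.0), (1, 1, 1))
    m = LabelMask(np.ones((3, 3, 3), dtype=np.uint8), (1, 1, 1))
    assert m.voxels.dtype == bool and m.count() == 27


def test_rescale_spacing_and_constant():
    vol = CTVolume(np.full((8, 8, 8), -77.0), (0.98, 0.98, 1.25))
    half = rescale_halved(vol)
    assert half.spacing == (1.96, 1.96, 2.5)
    assert half.shape == (4, 4, 4)
    assert np.allclose(half.voxels, -77.0)


def test_rescale_block_means_hand_computed():
    """A 4^3 volume of distinct values halves to the eight 2^3 block means."""
    v = np.arange(64, dtype=float).reshape(4, 4, 4)
    half = rescale_halved(CTVolume(v, (1, 1, 1)))
    for i in range(2):
        for j in range(2):
            for k in range(2):
                block = v[2 * i: 2 * i + 2, 2 * j: 2 * j + 2, 2 * k: 2 * k + 2]
                assert half.voxels[i, j, k] == pytest.approx(block.mean())


def test_rescale_drops_odd_trailing_voxels():
    v = np.zeros((5, 4, 7))
    half = rescale_halved(CTVolume(v, (1, 1, 1)))
    assert half.shape == (2, 2, 3)


def test_rescale_physical_extent_nearly_preserved():
    vol = CTVolume(np.zeros((10, 11, 12)), (0.98, 0.98, 1.25))
    half = rescale_halved(vol)
    for n, s, hn, hs, orig_s in zip(vol.shape, vol.spacing, half.shape,
                                    half.spacing, vol.spacing):
        assert abs(n * s - hn * hs) < orig_s * 2 + 1e-9


@pytest.mark.parametrize("suffix", [".nii.gz", ".mha"])
def test_volume_round_trip(tmp_path, suffix):
    rng = np.random.default_rng(0)
    vol = CTVolume(rng.integers(-1000, 1000, (6, 5, 4)).astype(float), (0.98, 0.98, 1.25))
    p = tmp_path / f"vol{suffix}"
    write_volume(vol, p)
    back = read_volume(p)
    assert back.spacing == pytest.approx(vol.spacing)
    assert (back.voxels == vol.voxels).all()


def test_mask_round_trip_and_sums(tmp_path):
    empty = LabelMask(np.zeros((4, 4, 4), bool), (1, 1, 1))
    one = LabelMask(np.eye(4, 4)[..., None].repeat(4, 2)[:, :, :4] > 2, (1, 1, 1))
    one.voxels[:] = False
    one.voxels[1, 2, 3] = True
    for name, m in [("empty", empty), ("one", one)]:
        p = tmp_path / f"{name}.mha"
        write_mask(m, p)
        back = read_volume(p)
        assert back.voxels.sum() == m.count()
        assert (back.voxels.astype(bool) == m.voxels).all()


def test_read_volume_errors(tmp_path):
    with pytest.raises(ValueError):
        read_volume(tmp_path / "vol.xyz")
    # 4D data is rejected
    import SimpleITK as sitk

    img4 = sitk.JoinSeries([sitk.Image(4, 4, 4, sitk.sitkInt16)] * 2)
    p = tmp_path / "vol4d.nii.gz"
    sitk.WriteImage(img4, str(p))
    with pytest.raises(ValueError):
        read_volume(p)


def test_read_volume_normalizes_flipped_z(tmp_path):
    """A volume stored superior-last is reordered so z index 0 is superior."""
    import SimpleITK as sitk

    vox = np.zeros((4, 4, 6))
    vox[:, :, 0] = 100.0  # our convention: slice 0 = most superior
    # store with axis 2 pointing Superior (so on disk, index 5 is most superior)
    arr = vox[:, :, ::-1].transpose(2, 1, 0)
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr))
    img.SetSpacing((1.0, 1.0, 2.0))
    img.SetDirection((1, 0, 0, 0, -1, 0, 0, 0, 1))  # L, A, S axes
    p = tmp_path / "flipped.nii.gz"
    sitk.WriteImage(img, str(p))
    back = read_volume(p)
    assert np.allclose(back.voxels[:, :, 0], 100.0)
    assert np.allclose(back.voxels[:, :, 1:], 0.0)


# --- DICOM series ---------------------------------------------------------

def _write_slice(path, z, pixels, series_uid="1.2.3.4", spacing=(0.98, 0.98),
                 drop=(), slope=1.0, intercept=-1024.0):
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.SeriesInstanceUID = series_uid
    ds.Modality = "CT"
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.ImagePositionPatient = [0.0, 0.0, float(z)]
    ds.PixelSpacing = list(spacing)
    ds.RescaleSlope = slope
    ds.RescaleIntercept = intercept
    ds.Rows, ds.Columns = pixels.shape
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelData = pixels.astype(np.uint16).tobytes()
    for attr in drop:
        delattr(ds, attr)
    ds.save_as(path, enforce_file_format=True)


def _series(tmp_path, zs, **kw):
    d = tmp_path / "series"
    d.mkdir(parents=True, exist_ok=True)
    for i, z in enumerate(zs):
        px = np.full((8, 6), 1024 + i, dtype=np.uint16)  # -> HU = i
        _write_slice(d / f"slice{i:03d}.dcm", z, px, **kw)
    return d


def test_dicom_series_spacing_and_hu(tmp_path):
    d = _series(tmp_path, zs=[10.0, 8.75, 7.5])  # superior-first already
    vol = read_dicom_series(d)
    assert vol.spacing == pytest.approx((0.98, 0.98, 1.25))
    assert vol.shape == (6, 8, 3)
    # slope/intercept applied: slice i has HU == i, superior (largest z) first
    assert np.allclose(vol.voxels[:, :, 0], 0.0)
    assert np.allclose(vol.voxels[:, :, 2], 2.0)


def test_dicom_reverse_order_is_normalized(tmp_path):
    fwd = read_dicom_series(_series(tmp_path / "a", zs=[10.0, 8.75, 7.5]))
    # same physical slices, written in reverse file/position order
    d = (tmp_path / "b" / "series")
    d.mkdir(parents=True)
    for i, z in enumerate([10.0, 8.75, 7.5]):
        px = np.full((8, 6), 1024 + i, dtype=np.uint16)
        _write_slice(d / f"slice{99 - i:03d}.dcm", z, px)
    rev = read_dicom_series(d)
    assert (rev.voxels == fwd.voxels).all()
    assert rev.spacing == fwd.spacing


def test_dicom_mixed_series_uid_rejected(tmp_path):
    d = _series(tmp_path, zs=[10.0, 8.75])
    px = np.full((8, 6), 1024, dtype=np.uint16)
    _write_slice(d / "intruder.dcm", 7.5, px, series_uid="9.9.9")
    with pytest.raises(ValueError, match="SeriesInstanceUID"):
        read_dicom_series(d)


def test_dicom_missing_spacing_rejected(tmp_path):
    d = _series(tmp_path, zs=[10.0, 8.75], drop=("PixelSpacing",))
    with pytest.raises(ValueError, match="PixelSpacing"):
        read_dicom_series(d)


def test_dicom_nonuniform_gaps_rejected(tmp_path):
    d = _series(tmp_path, zs=[10.0, 8.75, 7.0])  # gaps 1.25 and 1.75
    with pytest.raises(ValueError, match="non-uniform"):
        read_dicom_series(d)
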