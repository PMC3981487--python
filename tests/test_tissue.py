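"""Trunk extraction and tissue segmentation rules on constructed geometries."""

import numpy as np
import pytest

from visfat.morphology import distance_from_boundary
from visfat.tissue import (Thresholds, TissueMaps, extract_trunk, segment_air,
                           segment_bone, segment_fat, segment_muscle)
from visfat.volume import CTVolume, LabelMask

SP = (1.96, 1.96, 2.5)
TH = Thresholds()


def vol_of(v):
    return CTVolume(np.asarray(v, float), SP)


def mask_of(v):
    return LabelMask(np.asarray(v, bool), SP)


def test_thresholds_ordering_enforced():
    with pytest.raises(ValueError):
        Thresholds(fat_low=-30.0, fat_high=-190.0)  # reversed (empty) window


def _torso_volume():
    """Elliptical torso (0 HU) with an internal gas pocket and a detached couch."""
    v = np.full((40, 40), -1000.0)
    x, y = np.mgrid[0:40, 0:40]
    torso = ((x - 20) / 14.0) ** 2 + ((y - 22) / 10.0) ** 2 <= 1
    couch = (np.abs(x - 20) <= 10) & (y >= 2) & (y <= 4)
    v[torso] = 0.0
    v[couch] = 60.0
    pocket = ((x - 20) ** 2 + (y - 22) ** 2) <= 4
    v = np.repeat(v[..., None], 8, axis=2)
    v[pocket, :] = -1000.0  # bowel-gas pocket fully inside the torso
    return vol_of(v), torso, couch, pocket


def test_trunk_keeps_torso_rejects_couch_includes_pocket():
    vol, torso, couch, pocket = _torso_volume()
    trunk = extract_trunk(vol, TH).voxels
    assert trunk[torso, :].all()
    assert not trunk[:, :, 4][couch].any()
    assert trunk[:, :, 4][pocket].all()
    # outside-air background touching the slice edge is excluded
    assert not trunk[0, 0].any()


def test_trunk_empty_volume_is_an_error():
    with pytest.raises(ValueError, match="no body"):
        extract_trunk(vol_of(np.full((6, 6, 6), -1000.0)), TH)


def test_trunk_empty_slices_stay_empty():
    vol, torso, _, _ = _torso_volume()
    v = vol.voxels.copy()
    v[:, :, 0] = -1000.0  # an empty cranial slice
    trunk = extract_trunk(vol_of(v), TH).voxels
    # closing (r=1.5) may reach 1 voxel into the empty slice from its solid
    # neighbour, but nothing appears away from the torso
    assert not trunk[:, :, 0][~torso].any()


def test_bone_blank_filling_recovers_medullary_core():
    v = np.full((20, 20, 20), 0.0)
    v[6:14, 6:14, 6:14] = 400.0          # bone shell
    v[9:12, 9:12, 9:12] = -50.0          # low-HU medullary cavity
    trunk = mask_of(np.ones((20, 20, 20)))
    bone = segment_bone(vol_of(v), trunk, TH).voxels
    assert bone[10, 10, 10]              # cavity recovered by blank filling
    assert bone[6:14, 6:14, 6:14].all()


def test_bone_dilation_bridges_two_voxel_gap():
    v = np.full((24, 24, 12), 0.0)
    v[4:10, 10:14, 4:8] = 400.0
    v[12:18, 10:14, 4:8] = 400.0  # 2-voxel gap along x from the first block
    trunk = mask_of(np.ones_like(v))
    bone = segment_bone(vol_of(v), trunk, TH).voxels
    # the dilated shells connect, so the largest component keeps both blocks
    assert bone[4:10, 10:14, 4:8].all() and bone[12:18, 10:14, 4:8].all()


def test_bone_empty_warns_not_raises(caplog):
    import logging

    v = np.zeros((8, 8, 8))
    with caplog.at_level(logging.WARNING, logger="visfat.tissue"):
        bone = segment_bone(vol_of(v), mask_of(np.ones_like(v)), TH)
    assert bone.count() == 0
    assert any("bone" in r.message for r in caplog.records)


def test_small_isolated_calcification_dropped():
    v = np.full((24, 24, 12), 0.0)
    v[4:12, 4:12, 2:10] = 400.0  # main skeleton
    v[20, 20, 6] = 400.0         # far-away speck
    trunk = mask_of(np.ones_like(v))
    bone = segment_bone(vol_of(v), trunk, TH).voxels
    assert not bone[20, 20, 6]


def test_muscle_component_rules_and_depth_trim():
    v = np.full((30, 30, 16), 0.0)
    trunk = mask_of(np.ones_like(v))
    # (a) 19-voxel blob deep inside -> volume rule rejects (19 < 20)
    v[14, 6:25, 8] = 50.0
    muscle = segment_muscle(vol_of(v), trunk, mask_of(np.zeros_like(v)), TH).voxels
    assert not muscle.any()
    # (b) 100-voxel blob overlapping one bone voxel -> rejected
    v[:] = 0.0
    v[10:15, 10:15, 6:10] = 50.0  # 100 voxels
    bone = np.zeros_like(v, bool)
    bone[10, 10, 6] = True
    muscle = segment_muscle(vol_of(v), trunk, mask_of(bone), TH).voxels
    assert not muscle.any()
    # without the bone overlap the same blob is kept where deep enough
    muscle = segment_muscle(vol_of(v), trunk, mask_of(np.zeros_like(v)), TH).voxels
    depth = distance_from_boundary(trunk)
    expected = (v >= 30) & (depth >= 5)
    assert (muscle == expected).all()


def test_muscle_sheet_trimmed_against_distance_oracle():
    """A wall sheet reaching the body surface keeps only its deep voxels."""
    v = np.full((24, 24, 16), 0.0)
    v[2:10, 8:16, 2:14] = 50.0  # sheet from near-surface to deep
    trunk = mask_of(np.ones_like(v))
    muscle = segment_muscle(vol_of(v), trunk, mask_of(np.zeros_like(v)), TH).voxels
    depth = distance_from_boundary(trunk)
    assert (muscle == ((v >= 30) & (depth >= 5))).all()
    assert muscle.any() and not (muscle & (depth < 5)).any()


def test_air_threshold_is_strict():
    v = np.full((8, 8, 8), 0.0)
    v[2, 2, 2] = -800.0   # lung-like
    v[3, 3, 3] = -220.0   # exactly at the bound: NOT air
    v[4, 4, 4] = -220.5   # just below: air
    v[5, 5, 5] = -190.0   # fat-valued: not air
    air = segment_air(vol_of(v), mask_of(np.ones_like(v)), TH).voxels
    assert air[2, 2, 2] and air[4, 4, 4]
    assert not air[3, 3, 3] and not air[5, 5, 5]


def test_fat_window_is_inclusive_on_both_ends():
    v = np.full((8, 8, 8), 0.0)
    v[1, 1, 1] = -190.0
    v[2, 2, 2] = -30.0
    v[3, 3, 3] = -29.0
    v[4, 4, 4] = -191.0
    trunk = mask_of(np.ones_like(v))
    empty = mask_of(np.zeros_like(v))
    fat = segment_fat(vol_of(v), trunk, empty, empty, empty, TH).voxels
    assert fat[1, 1, 1] and fat[2, 2, 2]
    assert not fat[3, 3, 3] and not fat[4, 4, 4]


def test_fat_gap_between_muscle_and_air_is_closed_away():
    """A 1-voxel fat crack between two excluded tissues is sealed by the
    r=1.0 closing of their union, and a clean fat region is untouched."""
    v = np.full((20, 20, 8), 0.0)
    v[4:9, 4:12, 2:6] = 50.0      # muscle block
    v[9, 4:12, 2:6] = -100.0      # 1-voxel fat crack
    v[10:15, 4:12, 2:6] = -800.0  # air block
    v[2, 16, 6] = -100.0          # isolated clean fat voxel
    trunk = mask_of(np.ones_like(v))
    bone = mask_of(np.zeros_like(v))
    muscle = mask_of(v >= 30)
    air = segment_air(vol_of(v), trunk, TH)
    fat = segment_fat(vol_of(v), trunk, bone, muscle, air, TH).voxels
    assert not fat[9, 6, 3]       # crack removed
    assert fat[2, 16, 6]          # clean fat retained


def test_fat_window_monotonicity():
    """Widening the adipose HU window never shrinks the fat mask."""
    rng = np.random.default_rng(5)
    v = rng.uniform(-300, 100, (12, 12, 12))
    trunk = mask_of(np.ones_like(v))
    empty = mask_of(np.zeros_like(v))
    prev = None
    for lo, hi in [(-100, -60), (-150, -40), (-190, -30)]:
        th = Thresholds(fat_low=lo, fat_high=hi)
        fat = segment_fat(vol_of(v), trunk, empty, empty, empty, th).voxels
        if prev is not None:
            assert (prev <= fat).all()
        prev = fat


def test_tissue_maps_invariants_on_phantom_runs(pipeline_runs):
    for _, _, res in pipeline_runs:
        res.tissues.validate()  # subset-of-trunk and fat disjointness
        t = res.tissues
        assert not (t.fat.voxels & (t.bone.voxels | t.muscle.voxels | t.air.voxels)).any()
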