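"""Segmentation agreement metrics and summary tables."""

import numpy as np
import pytest

from thalparc import (
    LabeledVolume,
    centroid,
    centroid_distance,
    dice,
    evaluate_pair,
    max_radius,
    pct_volume_difference,
    summarize,
)
from thalparc.evaluation import records_to_frame


def _sets_from_masks(a_mask, b_mask):
    shape = (20, 5, 5)
    a = np.zeros(shape, bool)
    b = np.zeros(shape, bool)
    a.reshape(-1)[a_mask] = True
    b.reshape(-1)[b_mask] = True
    return a, b


def test_dice_identical_sets_is_one(rng):
    a = rng.random((5, 5, 5)) > 0.5
    assert dice(a, a) == 1.0


def test_dice_disjoint_sets_is_zero():
    a, b = _sets_from_masks(range(10), range(10, 20))
    assert dice(a, b) == 0.0


def test_dice_hand_counted_example():
    """|a| = 8, |b| = 10, |a∩b| = 6 -> 12/18."""
    a, b = _sets_from_masks(range(8), range(2, 12))
    assert np.isclose(dice(a, b), 12.0 / 18.0, atol=1e-12)


def test_dice_union_form_equals_classical_form(rng):
    """2|a∩b|/(|a∩b|+|a∪b|) == 2|a∩b|/(|a|+|b|) on 1000 random pairs."""
    for _ in range(1000):
        a = rng.random(60) > rng.random()
        b = rng.random(60) > rng.random()
        inter = np.count_nonzero(a & b)
        union = np.count_nonzero(a | b)
        classical = 2 * inter / (a.sum() + b.sum()) if (a.sum() + b.sum()) else 0.0
        ours = dice(a.reshape(4, 15, 1), b.reshape(4, 15, 1))
        assert np.isclose(ours, classical, atol=1e-12)
        if union:
            assert np.isclose(ours, 2 * inter / (inter + union), atol=1e-12)


def test_dice_symmetric(rng):
    a = rng.random((6, 6, 6)) > 0.6
    b = rng.random((6, 6, 6)) > 0.6
    assert dice(a, b) == dice(b, a)


def test_dice_empty_sets_convention():
    empty = np.zeros((3, 3, 3), bool)
    with pytest.warns(UserWarning):
        assert dice(empty, empty) == 0.0


def test_pct_volume_difference_hand_arithmetic():
    assert pct_volume_difference(100, 100) == 0.0
    assert pct_volume_difference(120, 100) == 20.0
    assert pct_volume_difference(80, 100) == -20.0


def test_pct_volume_difference_antisymmetry_relation():
    va, vb = 120.0, 100.0
    lhs = pct_volume_difference(va, vb)
    rhs = -pct_volume_difference(vb, va) * va / vb
    assert np.isclose(lhs, rhs, atol=1e-12)


def test_pct_volume_difference_zero_reference_rejected():
    with pytest.raises(ValueError):
        pct_volume_difference(10, 0)


def _vol(labels, affine=None, table=None):
    labels = np.asarray(labels, dtype=np.int32)
    table = table or {c: f"label{c}" for c in set(np.unique(labels)) - {0}}
    return LabeledVolume(labels, affine if affine is not None else np.eye(4), table)


def test_centroid_single_voxel_world_coordinate():
    labels = np.zeros((4, 4, 4), np.int32)
    labels[1, 2, 3] = 1
    affine = np.diag([2.0, 2.0, 2.5, 1.0])
    affine[:3, 3] = [-10, -10, -10]
    assert np.allclose(centroid(_vol(labels, affine), 1), [-8.0, -6.0, -2.5])


def test_centroid_symmetric_pair_midpoint():
    labels = np.zeros((5, 5, 5), np.int32)
    labels[0, 2, 2] = labels[4, 2, 2] = 1
    assert np.allclose(centroid(_vol(labels), 1), [2.0, 2.0, 2.0])


def test_centroid_through_affine_hand_computed():
    labels = np.zeros((4, 4, 4), np.int32)
    labels[0, 0, 0] = labels[1, 0, 0] = labels[2, 3, 1] = 1
    affine = np.array([[2, 0, 0, 1], [0, 3, 0, -1], [0, 0, 1, 0], [0, 0, 0, 1]], float)
    # voxels (0,0,0),(1,0,0),(2,3,1) -> world (1,-1,0),(3,-1,0),(5,8,1); mean = (3,2,1/3)
    assert np.abs(centroid(_vol(labels, affine), 1) - [3.0, 2.0, 1.0 / 3.0]).max() < 1e-12


def test_centroid_missing_code_raises():
    with pytest.raises(KeyError):
        centroid(_vol(np.ones((2, 2, 2))), 5)


def test_centroid_distance_345_triangle():
    assert centroid_distance([0, 0, 0], [3, 4, 0]) == 5.0
    assert centroid_distance([1, 1, 1], [1, 1, 1]) == 0.0


def test_centroid_distance_rigid_invariance(rng):
    p1, p2 = rng.normal(size=(2, 3))
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    t = rng.normal(size=3)
    d0 = centroid_distance(p1, p2)
    d1 = centroid_distance(q @ p1 + t, q @ p2 + t)
    assert np.isclose(d0, d1, atol=1e-9)


def test_max_radius_examples():
    labels = np.zeros((5, 5, 5), np.int32)
    labels[2, 2, 2] = 1
    assert max_radius(_vol(labels), 1) == 0.0
    labels = np.zeros((5, 5, 5), np.int32)
    labels[0, 0, 0] = labels[4, 0, 0] = 2  # 4 mm apart at unit voxels
    assert max_radius(_vol(labels), 2) == 2.0


def test_max_radius_dominates_all_centroid_distances(rng):
    labels = (rng.random((6, 6, 6)) > 0.7).astype(np.int32)
    vol = _vol(labels)
    r = max_radius(vol, 1)
    c = centroid(vol, 1)
    for v in np.argwhere(labels == 1):  # brute-force max property
        assert r >= np.linalg.norm(vol.world_coords(v)[0] - c) - 1e-12


def test_evaluate_pair_identical_parcellations(rng):
    labels = rng.integers(0, 4, size=(6, 6, 6)).astype(np.int32)
    vol = _vol(labels)
    records = evaluate_pair(vol, vol)
    assert len(records) == len(vol.codes)
    for r in records:
        assert r.dice == 1.0
        assert r.pct_vol_diff == 0.0
        assert r.centroid_distance_mm == 0.0
        assert not r.missing


def test_evaluate_pair_toy_hand_computed():
    a = np.zeros((4, 4, 1), np.int32)
    b = np.zeros((4, 4, 1), np.int32)
    a[:2, :2] = 1   # 4 voxels
    b[:2, :3] = 1   # 6 voxels, intersection 4
    a[3, :2] = 2
    b[3, :2] = 2
    table = {1: "L-A", 2: "L-VA"}
    recs = evaluate_pair(_vol(a, table=table), _vol(b, table=table))
    r1 = next(r for r in recs if r.nucleus_code == 1)
    assert np.isclose(r1.dice, 2 * 4 / (4 + 6), atol=1e-9)
    assert np.isclose(r1.pct_vol_diff, (4 - 6) / 6 * 100, atol=1e-9)
    # centroids: a over rows 0-1 cols 0-1 -> (0.5, 0.5); b cols 0-2 -> (0.5, 1.0)
    assert np.isclose(r1.centroid_distance_mm, 0.5, atol=1e-9)
    r2 = next(r for r in recs if r.nucleus_code == 2)
    assert r2.dice == 1.0 and r2.hemisphere == "left"


def test_evaluate_pair_missing_codes_flagged():
    a = np.zeros((3, 3, 1), np.int32)
    b = np.zeros((3, 3, 1), np.int32)
    a[0] = 1
    b[0] = 1
    b[2] = 2
    recs = evaluate_pair(_vol(a), _vol(b, table={1: "label1", 2: "label2"}))
    assert len(recs) == 2
    missing = [r for r in recs if r.missing]
    assert len(missing) == 1 and missing[0].nucleus_code == 2


def test_evaluate_pair_no_shared_codes_rejected():
    a = np.zeros((3, 3, 1), np.int32)
    b = np.zeros((3, 3, 1), np.int32)
    a[0] = 1
    b[0] = 2
    with pytest.raises(ValueError, match="share"):
        evaluate_pair(_vol(a), _vol(b))


def test_summarize_hand_values(rng):
    labels = np.zeros((4, 4, 1), np.int32)
    labels[:2] = 1
    vol = _vol(labels, table={1: "L-A"})
    records = []
    for d in (1.0, 2.0, 3.0):
        recs = evaluate_pair(vol, vol)
        recs[0].dice = d
        records.extend(recs)
    table = summarize(records)
    assert len(table) == 1
    row = table.iloc[0]
    assert row["n"] == 3
    assert np.isclose(row["dice_mean"], 2.0)
    assert np.isclose(row["dice_sd"], 1.0)  # n-1 denominator
    assert np.isclose(row["dice_median"], 2.0)


def test_summarize_single_record_sd_zero():
    labels = np.zeros((3, 3, 1), np.int32)
    labels[0] = 1
    vol = _vol(labels)
    table = summarize(evaluate_pair(vol, vol))
    assert table.iloc[0]["n"] == 1
    assert table.iloc[0]["dice_sd"] == 0.0


def test_summarize_empty_rejected():
    import pandas as pd

    with pytest.raises(ValueError):
        summarize(pd.DataFrame())


def test_metrics_invariant_under_shared_relabeling_of_grid(rng):
    a = rng.integers(0, 3, size=(5, 5, 5)).astype(np.int32)
    b = rng.integers(0, 3, size=(5, 5, 5)).astype(np.int32)
    perm = rng.permutation(5)
    d0 = dice(a == 1, b == 1)
    d1 = dice((a[perm] == 1), (b[perm] == 1))
    assert d0 == d1


def test_records_frame_columns():
    labels = np.zeros((3, 3, 1), np.int32)
    labels[0] = 1
    vol = _vol(labels)
    frame = records_to_frame(evaluate_pair(vol, vol))
    assert {"nucleus_code", "dice", "pct_vol_diff", "centroid_distance_mm"} <= set(frame.columns)
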