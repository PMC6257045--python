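"""Combined-metric k-means: metric, initialization, recovery, relabeling, QC."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from thalparc import (
    ClusteringConfig,
    LabeledVolume,
    combined_distance,
    init_centroids,
    qc_parcellation,
    relabel_to_reference,
    run_modified_kmeans,
)
from thalparc.clustering import ClusterModel, Parcellation


def _blobs(rng, k=3, per=30, spatial_gap=40.0, feature_gap=1.0, n_coeff=28):
    """k spatially and feature-separated blobs with ground-truth labels."""
    positions, features, truth = [], [], []
    protos = rng.normal(size=(k, n_coeff)) * 0.01
    for j in range(k):
        protos[j, j] += feature_gap
        center = np.array([j * spatial_gap, 0.0, 0.0])
        positions.append(center + rng.normal(0, 1.0, size=(per, 3)))
        features.append(protos[j] + rng.normal(0, 0.01, size=(per, n_coeff)))
        truth.extend([j] * per)
    return np.vstack(positions), np.vstack(features), np.array(truth)


def test_combined_distance_zero_at_centroid():
    cfg = ClusteringConfig()
    assert combined_distance([1, 2, 3], np.zeros(5), [1, 2, 3], np.zeros(5), cfg) == 0.0


def test_combined_distance_spatial_limit():
    cfg = ClusteringConfig(w_spatial=1.0, w_feature=0.0)
    d = combined_distance([0, 0, 0], np.ones(4), [3, 4, 0], np.zeros(4), cfg)
    assert np.isclose(d, 5.0)


def test_combined_distance_hand_arithmetic():
    """2 mm spatial + 4 scaled-feature units at 0.5/0.5 weights -> 3."""
    cfg = ClusteringConfig()
    f = np.zeros(4)
    f2 = np.zeros(4)
    f2[0] = 4.0
    assert np.isclose(combined_distance([0, 0, 0], f, [2, 0, 0], f2, cfg), 3.0)


def test_combined_distance_dimension_mismatch():
    with pytest.raises(ValueError):
        combined_distance([0, 0], np.zeros(3), [0, 0, 0], np.zeros(3), ClusteringConfig())


def test_init_single_run_equals_that_run(rng):
    pos = rng.normal(size=(50, 3)) * 10
    one = init_centroids(pos, 3, n_runs=1, seed=5)
    again = init_centroids(pos, 3, n_runs=1, seed=5)
    assert np.array_equal(one, again)


def test_init_deterministic(rng):
    pos = rng.normal(size=(60, 3)) * 10
    assert np.array_equal(
        init_centroids(pos, 4, n_runs=20, seed=3), init_centroids(pos, 4, n_runs=20, seed=3)
    )


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_init_recovers_separated_blobs(seed, rng):
    centers = np.array([[0, 0, 0], [50, 0, 0], [0, 50, 0]], dtype=float)
    pos = np.vstack([c + rng.normal(0, 1.5, size=(40, 3)) for c in centers])
    averaged = init_centroids(pos, 3, n_runs=30, seed=seed)
    d = np.linalg.norm(averaged[:, None] - centers[None], axis=2)
    assert np.all(d.min(axis=1) < 5.0)  # each averaged centroid inside a blob


def test_kmeans_recovers_planted_partition(rng):
    pos, feats, truth = _blobs(rng)
    cfg = ClusteringConfig(k=3, n_init_runs=20, seed=2)
    parc = run_modified_kmeans(pos, feats, cfg)
    assert adjusted_rand_score(truth, parc.assignment) == 1.0
    assert parc.converged


def test_kmeans_k1_gives_global_means(rng):
    pos = rng.normal(size=(20, 3))
    feats = rng.normal(size=(20, 5))
    cfg = ClusteringConfig(k=1, n_init_runs=3, seed=0)
    parc = run_modified_kmeans(pos, feats, cfg)
    assert np.all(parc.assignment == 0)
    assert np.allclose(parc.model.spatial_centroids[0], pos.mean(axis=0))
    assert np.allclose(parc.model.feature_centroids[0], (feats * cfg.feature_scale).mean(axis=0))


def _brute_force_fixed_point(parc, positions, features):
    """Every voxel must sit with its combined-distance-nearest centroid."""
    cfg = parc.model.config
    scaled = features * cfg.feature_scale
    for i in range(len(positions)):
        d = [
            combined_distance(
                positions[i], scaled[i],
                parc.model.spatial_centroids[j], parc.model.feature_centroids[j], cfg,
            )
            for j in range(cfg.k)
        ]
        if d[parc.assignment[i]] > min(d) + 1e-12:
            return False
    return True


def test_converged_assignment_is_brute_force_fixed_point(rng):
    for trial in range(10):
        n = int(rng.integers(10, 41))
        pos = rng.normal(size=(n, 3)) * 5
        feats = rng.normal(size=(n, 6)) * 0.05
        cfg = ClusteringConfig(k=2, n_init_runs=5, seed=trial)
        parc = run_modified_kmeans(pos, feats, cfg)
        assert parc.converged
        assert _brute_force_fixed_point(parc, pos, feats)


def test_squared_metric_objective_monotone(rng):
    pos, feats, _ = _blobs(rng, spatial_gap=8.0, feature_gap=0.3)
    cfg = ClusteringConfig(k=3, n_init_runs=10, seed=4, squared_metric=True)
    parc = run_modified_kmeans(pos, feats, cfg)
    trace = parc.objective_trace
    assert len(trace) >= 1
    assert all(a >= b - 1e-9 for a, b in zip(trace, trace[1:]))


def test_scale_consistency_power_of_two(rng):
    """features * c with feature_scale / c gives the identical assignment."""
    pos, feats, _ = _blobs(rng)
    c = 4.0  # exactly representable: (f*c)*(s/c) == f*s in binary fp
    a = run_modified_kmeans(pos, feats, ClusteringConfig(k=3, n_init_runs=10, seed=6))
    b = run_modified_kmeans(
        pos, feats * c, ClusteringConfig(k=3, n_init_runs=10, seed=6, feature_scale=100.0 / c)
    )
    assert np.array_equal(a.assignment, b.assignment)


def test_permutation_equivariance(rng):
    pos, feats, _ = _blobs(rng)
    perm = rng.permutation(len(pos))
    a = run_modified_kmeans(pos, feats, ClusteringConfig(k=3, n_init_runs=10, seed=8))
    b = run_modified_kmeans(pos[perm], feats[perm], ClusteringConfig(k=3, n_init_runs=10, seed=8))
    assert adjusted_rand_score(a.assignment[perm], b.assignment) == 1.0


def _toy_parcellation(assignment, voxels, k):
    cfg = ClusteringConfig(k=k, n_init_runs=1, seed=0)
    model = ClusterModel(np.zeros((k, 3)), np.zeros((k, 2)), cfg)
    return Parcellation(
        assignment=np.asarray(assignment), model=model, objective=0.0,
        voxels=np.asarray(voxels), affine=np.eye(4),
    )


def test_relabel_recovers_permuted_reference():
    voxels = np.argwhere(np.ones((4, 4, 1), bool))
    ref_labels = np.zeros((4, 4, 1), dtype=np.int32)
    ref_labels[:2, :2] = 1
    ref_labels[:2, 2:] = 2
    ref_labels[2:, :2] = 3
    ref_labels[2:, 2:] = 4
    ref = LabeledVolume(ref_labels, np.eye(4), {1: "A", 2: "B", 3: "C", 4: "D"})
    perm = {1: 2, 2: 0, 3: 3, 4: 1}  # cluster index = perm[true code]
    assignment = np.vectorize(perm.get)(ref_labels[tuple(voxels.T)])
    out = relabel_to_reference(_toy_parcellation(assignment, voxels, 4), ref)
    assert np.array_equal(out.labels, ref.labels)
    assert out.label_table == ref.label_table


def test_relabel_matches_exhaustive_permutation_search(rng):
    voxels = np.argwhere(np.ones((3, 3, 3), bool))
    ref_labels = (rng.integers(0, 3, size=27) + 1).reshape(3, 3, 3).astype(np.int32)
    ref = LabeledVolume(ref_labels, np.eye(4), {1: "A", 2: "B", 3: "C"})
    assignment = rng.integers(0, 3, size=27)
    parc = _toy_parcellation(assignment, voxels, 3)
    out = relabel_to_reference(parc, ref)

    ref_flat = ref_labels[tuple(voxels.T)]
    best_score = max(
        sum(np.count_nonzero((assignment == c) & (ref_flat == perm[c])) for c in range(3))
        for perm in itertools.permutations([1, 2, 3])
    )
    out_flat = out.labels[tuple(voxels.T)]
    produced = {c: out_flat[assignment == c][0] for c in range(3)}
    assert all(np.all(out_flat[assignment == c] == code) for c, code in produced.items())
    out_score = sum(
        np.count_nonzero((assignment == c) & (ref_flat == code)) for c, code in produced.items()
    )
    assert out_score == best_score


def test_relabel_k_mismatch_rejected():
    voxels = np.argwhere(np.ones((2, 2, 1), bool))
    ref = LabeledVolume(np.ones((2, 2, 1), dtype=np.int32), np.eye(4), {1: "A"})
    parc = _toy_parcellation(np.array([0, 1, 0, 1]), voxels, 2)
    with pytest.raises(ValueError, match="expected k"):
        relabel_to_reference(parc, ref)


def test_qc_clean_parcellation_unflagged(rng):
    voxels = []
    assignment = []
    for j in range(7):
        block = np.argwhere(np.ones((3, 3, 3), bool)) + np.array([j * 5, 0, 0])
        voxels.append(block)
        assignment.extend([j] * len(block))
    parc = _toy_parcellation(np.array(assignment), np.vstack(voxels), 7)
    assert qc_parcellation(parc).ok


def test_qc_min_fraction_flag():
    big = np.argwhere(np.ones((10, 10, 10), bool))
    tiny = np.array([[20, 0, 0], [20, 0, 1]])
    assignment = np.r_[np.zeros(len(big), int), np.ones(len(tiny), int)]
    parc = _toy_parcellation(assignment, np.vstack([big, tiny]), 2)
    report = qc_parcellation(parc)
    assert any("below floor" in f for f in report.flags)


def test_qc_fragmentation_flag():
    island1 = np.argwhere(np.ones((3, 3, 3), bool))
    island2 = island1 + np.array([10, 0, 0])
    other = np.argwhere(np.ones((3, 3, 3), bool)) + np.array([20, 0, 0])
    voxels = np.vstack([island1, island2, other])
    assignment = np.r_[np.zeros(len(island1) + len(island2), int), np.ones(len(other), int)]
    parc = _toy_parcellation(assignment, voxels, 2)
    report = qc_parcellation(parc)
    assert any("fragmented" in f for f in report.flags)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        ClusteringConfig(w_spatial=0.7, w_feature=0.5)
    with pytest.raises(ValueError):
        ClusteringConfig(feature_scale=0.0)
    with pytest.raises(ValueError):
        ClusteringConfig(k=0)
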