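"""Spatially constrained k-means on combined position + ODF-feature distances.

Each thalamus is partitioned into ``k`` clusters (default 7) by a modified
k-means whose assignment metric is a weighted sum of two Euclidean
distances: voxel position in world millimetres, and the (scaled) SH
coefficient vector.  Equal weights (0.5 / 0.5) make the feature term group
voxels with similar microstructure while the spatial term keeps clusters
compact and contiguous.

Initialization is data-driven: many (default 5000) randomly initialized
position-only k-means runs are aligned to each other by minimum-cost
centroid matching and averaged; the averaged spatial centroids seed the
combined-metric Lloyd iterations.

The default metric sums unsquared Euclidean distances; the arithmetic-mean
centroid update is then a heuristic rather than the exact minimizer, so the
objective is not guaranteed monotone (convergence is still declared on a
fixed point of the assignment).  ``squared_metric=True`` squares each term,
which is equivalent to plain k-means on concatenated scaled vectors and has
a provably non-increasing objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from scipy import ndimage
from sklearn.cluster import KMeans

from .types import LabeledVolume


@dataclass(frozen=True)
class ClusteringConfig:
    k: int = 7
    w_spatial: float = 0.5
    w_feature: float = 0.5
    feature_scale: float = 100.0
    n_init_runs: int = 5000
    max_iter: int = 300
    seed: int = 0
    squared_metric: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.w_spatial < 0 or self.w_feature < 0:
            raise ValueError("weights must be non-negative")
        if abs(self.w_spatial + self.w_feature - 1.0) > 1e-9:
            raise ValueError("w_spatial + w_feature must equal 1")
        if self.feature_scale <= 0:
            raise ValueError("feature_scale must be positive")
        if self.n_init_runs < 1 or self.max_iter < 1:
            raise ValueError("n_init_runs and max_iter must be >= 1")


@dataclass
class ClusterModel:
    """Paired spatial (mm) and feature (scaled SH) centroids."""

    spatial_centroids: np.ndarray  # (k, 3)
    feature_centroids: np.ndarray  # (k, n_coeff)
    config: ClusteringConfig

    def __post_init__(self) -> None:
        self.spatial_centroids = np.asarray(self.spatial_centroids, dtype=float)
        self.feature_centroids = np.asarray(self.feature_centroids, dtype=float)
        k = self.config.k
        if len(self.spatial_centroids) != k or len(self.feature_centroids) != k:
            raise ValueError("need exactly k centroids of each kind")
        if not (np.all(np.isfinite(self.spatial_centroids)) and np.all(np.isfinite(self.feature_centroids))):
            raise ValueError("centroids must be finite")


@dataclass
class Parcellation:
    """Cluster index per mask voxel, with the model that produced it."""

    assignment: np.ndarray  # (N,) in [0, k)
    model: ClusterModel
    objective: float
    voxels: np.ndarray | None = None  # (N, 3) voxel coords, optional geometry
    affine: np.ndarray | None = None
    n_iter: int = 0
    converged: bool = True
    objective_trace: list[float] = field(default_factory=list)


def combined_distance(position, features, spatial_centroid, feature_centroid, cfg: ClusteringConfig) -> float:
    """Weighted spatial + feature distance of one voxel to one centroid."""
    position = np.asarray(position, dtype=float)
    features = np.asarray(features, dtype=float)
    spatial_centroid = np.asarray(spatial_centroid, dtype=float)
    feature_centroid = np.asarray(feature_centroid, dtype=float)
    if position.shape != spatial_centroid.shape or features.shape != feature_centroid.shape:
        raise ValueError("dimension mismatch between voxel and centroid")
    ds = np.linalg.norm(position - spatial_centroid)
    df = np.linalg.norm(features - feature_centroid)
    if cfg.squared_metric:
        ds, df = ds**2, df**2
    return float(cfg.w_spatial * ds + cfg.w_feature * df)


def _distance_matrix(positions, features, model: ClusterModel) -> np.ndarray:
    cfg = model.config
    ds = cdist(positions, model.spatial_centroids)
    df = cdist(features, model.feature_centroids)
    if cfg.squared_metric:
        ds, df = ds**2, df**2
    return cfg.w_spatial * ds + cfg.w_feature * df


def _run_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def init_centroids(positions: np.ndarray, k: int, n_runs: int, seed: int) -> np.ndarray:
    """Averaged-restart position-only initialization.

    Runs ``n_runs`` independently seeded randomly-initialized (k-means++
    seeding) k-means on the voxel positions alone, aligns every run's
    centroids to the first run's by minimum-cost one-to-one matching, and
    returns the element-wise average.
    Positions are canonicalized to lexicographic order first so the result
    depends only on the voxel set, not its ordering.
    """
    positions = np.asarray(positions, dtype=float)
    if len(positions) <= k:
        raise ValueError("need more voxels than clusters")
    order = np.lexsort(positions.T[::-1])
    pos = positions[order]
    seeds = _run_seeds(seed, n_runs)
    reference = None
    total = np.zeros((k, pos.shape[1]))
    for s in seeds:
        km = KMeans(n_clusters=k, init="k-means++", n_init=1, max_iter=100, random_state=int(s))
        km.fit(pos)
        centers = km.cluster_centers_
        if np.unique(km.labels_).size < k:
            raise RuntimeError("position-only k-means produced an empty cluster")
        if reference is None:
            reference = centers
            aligned = centers
        else:
            rows, cols = linear_sum_assignment(cdist(reference, centers))
            aligned = centers[cols[np.argsort(rows)]]
        total += aligned
    return total / n_runs


def run_modified_kmeans(positions: np.ndarray, features: np.ndarray, cfg: ClusteringConfig) -> Parcellation:
    """Lloyd iterations under the combined spatial + feature metric.

    ``features`` enter unscaled and are multiplied by ``cfg.feature_scale``.
    Initial feature centroids are per-cluster mean features over the
    partition induced by spatial distance to the averaged initial centroids.
    An empty cluster is repaired by re-seeding its centroid at the voxel
    currently farthest from its own centroid.
    """
    positions = np.asarray(positions, dtype=float)
    features = np.asarray(features, dtype=float) * cfg.feature_scale
    n = len(positions)
    if len(features) != n:
        raise ValueError("positions and features must align")
    if n <= cfg.k:
        raise ValueError("need more voxels than clusters")

    spatial_c = init_centroids(positions, cfg.k, cfg.n_init_runs, cfg.seed)
    nearest = np.argmin(cdist(positions, spatial_c), axis=1)
    feature_c = np.empty((cfg.k, features.shape[1]))
    for j in range(cfg.k):
        members = nearest == j
        if members.any():
            feature_c[j] = features[members].mean(axis=0)
        else:  # seed from the voxel spatially closest to this centroid
            feature_c[j] = features[np.argmin(cdist(positions, spatial_c[j : j + 1]).ravel())]

    model = ClusterModel(spatial_c, feature_c, cfg)
    assignment = np.full(n, -1)
    converged = False
    n_iter = 0
    trace: list[float] = []
    for n_iter in range(1, cfg.max_iter + 1):
        dist = _distance_matrix(positions, features, model)
        new_assignment = np.argmin(dist, axis=1)

        repairs = 0
        while True:
            counts = np.bincount(new_assignment, minlength=cfg.k)
            empty = np.flatnonzero(counts == 0)
            if empty.size == 0:
                break
            repairs += 1
            if repairs > cfg.k + 1:
                raise RuntimeError("empty-cluster repair did not terminate")
            d_own = dist[np.arange(n), new_assignment]
            j = empty[0]
            far = int(np.argmax(d_own))
            model.spatial_centroids[j] = positions[far]
            model.feature_centroids[j] = features[far]
            dist = _distance_matrix(positions, features, model)
            new_assignment = np.argmin(dist, axis=1)

        trace.append(float(dist[np.arange(n), new_assignment].sum()))
        if np.array_equal(new_assignment, assignment):
            converged = True
            break
        assignment = new_assignment
        for j in range(cfg.k):
            members = assignment == j
            model.spatial_centroids[j] = positions[members].mean(axis=0)
            model.feature_centroids[j] = features[members].mean(axis=0)

    dist = _distance_matrix(positions, features, model)
    objective = float(dist[np.arange(n), assignment].sum())
    return Parcellation(
        assignment=assignment,
        model=model,
        objective=objective,
        n_iter=n_iter,
        converged=converged,
        objective_trace=trace,
    )


def relabel_to_reference(parcellation: Parcellation, reference: LabeledVolume) -> LabeledVolume:
    """Rename clusters with reference label codes by maximum-overlap matching.

    Solves the one-to-one assignment between the ``k`` clusters and the
    ``k`` reference codes that maximizes total voxel overlap, then emits a
    volume using the reference codes and names.  The parcellation must carry
    voxel geometry (``voxels``/``affine``) on the reference grid.
    """
    if parcellation.voxels is None or parcellation.affine is None:
        raise ValueError("parcellation lacks voxel geometry")
    voxels = parcellation.voxels
    ref_codes = reference.labels[tuple(voxels.T)]
    codes = sorted(set(np.unique(ref_codes)) - {0})
    k = parcellation.model.config.k
    if len(codes) != k:
        raise ValueError(f"reference has {len(codes)} labels on the voxel set, expected k={k}")
    overlap = np.zeros((k, k))
    for j, code in enumerate(codes):
        in_code = ref_codes == code
        for c in range(k):
            overlap[c, j] = np.count_nonzero(in_code & (parcellation.assignment == c))
    rows, cols = linear_sum_assignment(-overlap)
    mapping = {int(r): codes[int(c)] for r, c in zip(rows, cols)}
    out = np.zeros(reference.labels.shape, dtype=reference.labels.dtype)
    out[tuple(voxels.T)] = np.vectorize(mapping.get)(parcellation.assignment)
    table = {code: reference.label_table[code] for code in codes}
    return LabeledVolume(labels=out, affine=reference.affine, label_table=table)


@dataclass
class QCReport:
    """Per-cluster size and fragmentation metrics with raised flags."""

    cluster_fraction: dict[int, float]
    n_sizeable_components: dict[int, int]
    flags: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.flags


def qc_parcellation(
    parcellation: Parcellation,
    min_fraction: float = 0.01,
    secondary_component_fraction: float = 0.10,
) -> QCReport:
    """Flag atypical outcomes: vanishing clusters or fragmented clusters.

    A cluster is fragmented when, after 26-connected component analysis,
    more than one component exceeds ``secondary_component_fraction`` of the
    cluster's size.  Flagged subjects are candidates for exclusion, mirroring
    manual review of unexpected segmentation patterns.
    """
    if parcellation.voxels is None:
        raise ValueError("parcellation lacks voxel geometry")
    n = len(parcellation.assignment)
    voxels = parcellation.voxels
    shape = tuple(voxels.max(axis=0) - voxels.min(axis=0) + 3)
    origin = voxels.min(axis=0) - 1
    structure = np.ones((3, 3, 3), dtype=bool)
    fractions: dict[int, float] = {}
    components: dict[int, int] = {}
    flags: list[str] = []
    for c in range(parcellation.model.config.k):
        members = voxels[parcellation.assignment == c]
        frac = len(members) / n
        fractions[c] = frac
        grid = np.zeros(shape, dtype=bool)
        grid[tuple((members - origin).T)] = True
        labeled, n_comp = ndimage.label(grid, structure=structure)
        sizes = np.bincount(labeled.ravel())[1:]
        sizeable = int(np.count_nonzero(sizes > secondary_component_fraction * max(1, len(members))))
        components[c] = sizeable
        if frac < min_fraction:
            flags.append(f"cluster {c}: fraction {frac:.4f} below floor {min_fraction}")
        if sizeable > 1:
            flags.append(f"cluster {c}: fragmented into {sizeable} sizeable components")
    return QCReport(cluster_fraction=fractions, n_sizeable_components=components, flags=flags)
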