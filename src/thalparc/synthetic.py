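"""Synthetic cohort generator.

Emulates the per-subject inputs the parcellation pipeline assumes, so the
full chain — mask refinement, feature extraction, clustering, atlas
building, evaluation — can be run and validated without scan data.

Each subject bundle contains two disjoint ellipsoidal "thalami".  A
template-space anatomy (ellipsoids plus ``k`` well-spread nucleus seed
points per hemisphere) is fixed by the cohort seed; each subject sees that
anatomy through the inverse of its own small rigid+scaling
subject-to-template transform, with the seed points jittered per subject.
Nuclei are the nearest-seed (Voronoi) cells inside the ellipsoid — convex,
hence compact and connected.  Every nucleus carries a distinct ODF
prototype: a sharp single-fiber (Watson-profile) ODF at a nucleus-specific
orientation projected onto the SH basis.  Per-voxel bootstrap stacks are
the prototype plus independent Gaussian coefficient noise, emulating
residual-bootstrap ODF sampling.

Tissue maps and FA are planted so the mask-refinement rules have a known
right answer: a CSF-probability rim (> 5%) of configurable width around
each thalamus and a high-FA (> 0.55) band on the lateral border emulating
internal-capsule contamination; both are recorded on the bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

from .io import ColorLUT
from .sh import SHBasis, build_basis, fit_sh, sphere_directions
from .types import LabeledVolume, voxel_to_world


class SizingError(ValueError):
    """The grid cannot host two ellipsoidal thalami with k clusters each."""


class SeparationError(RuntimeError):
    """Prototype orientations could not achieve the requested separation."""


NUCLEUS_NAMES_7 = ("A", "VA", "MD", "VLV", "VLD", "Pu", "CL-LP-PuM")

_PALETTE_7 = (
    (220, 20, 60),
    (255, 165, 0),
    (255, 255, 0),
    (0, 200, 80),
    (0, 160, 255),
    (140, 70, 255),
    (255, 105, 180),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Conditions of the synthetic study.

    Defaults mirror the pipeline's operating point: k = 7 nuclei per
    hemisphere, SH order 6 (28 coefficients), 50 bootstrap samples, and
    2 x 2 x 2.5 mm voxels.  ``feature_noise_sd`` is the per-sample Gaussian
    sd on SH coefficients; prototypes are generated with minimum pairwise
    separation ``prototype_separation``, so the default contrast-to-noise
    ratio is 0.4 / 0.1 = 4 (and the 50-sample mean shrinks the effective
    noise by a further factor of ~7).
    """

    grid_shape: tuple[int, int, int] = (32, 24, 16)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.5)
    n_subjects: int = 10
    k_per_hemisphere: int = 7
    sh_order: int = 6
    n_bootstrap_samples: int = 50
    feature_noise_sd: float = 0.1
    spatial_jitter_mm: float = 1.0
    transform_magnitude: float = 2.0
    csf_rim_width_vox: int = 1
    prototype_separation: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(s < 1 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")
        for name in ("n_subjects", "k_per_hemisphere", "n_bootstrap_samples"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.sh_order < 0 or self.sh_order % 2 != 0:
            raise ValueError("sh_order must be even and non-negative")
        for name in ("feature_noise_sd", "spatial_jitter_mm", "transform_magnitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.csf_rim_width_vox < 0:
            raise ValueError("csf_rim_width_vox must be non-negative")


@dataclass
class SubjectBundle:
    """All per-subject inputs the pipeline consumes, plus ground truth.

    ``odf_samples`` has shape (n_mask_voxels, n_bootstrap_samples, n_coeff)
    and rows align with ``mask_voxels`` (raster order).  ``csf_rim`` and
    ``fa_rim`` record the planted contamination that mask refinement is
    expected to remove.
    """

    thalamus_mask: np.ndarray
    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    fa: np.ndarray
    mask_voxels: np.ndarray
    odf_samples: np.ndarray
    true_labels: LabeledVolume
    to_template: np.ndarray  # 4x4 subject-world -> template-world
    csf_rim: np.ndarray = field(repr=False, default=None)
    fa_rim: np.ndarray = field(repr=False, default=None)


def default_lut(k_per_hemisphere: int = 7) -> ColorLUT:
    """Bilateral LUT: colors symmetric between hemispheres, codes unique.

    Left hemisphere takes codes ``1..k``, right ``k+1..2k``; for k = 7 the
    anatomical group names A, VA, MD, VLV, VLD, Pu, CL-LP-PuM are used.
    """
    k = k_per_hemisphere
    names = NUCLEUS_NAMES_7 if k == 7 else tuple(f"N{i + 1}" for i in range(k))
    palette = [_PALETTE_7[i % len(_PALETTE_7)] for i in range(k)]
    records: dict[int, tuple[str, int, int, int, int]] = {}
    for i in range(k):
        r, g, b = palette[i]
        records[i + 1] = (f"L-{names[i]}", r, g, b, 255)
    for i in range(k):
        r, g, b = palette[i]
        records[k + i + 1] = (f"R-{names[i]}", r, g, b, 255)
    return ColorLUT(records)


def make_cluster_prototypes(
    k: int,
    basis: SHBasis,
    separation: float,
    seed: int,
    kappa: float = 16.0,
    max_tries: int = 50,
) -> np.ndarray:
    """``k`` unit-norm SH coefficient vectors with pairwise distance >= separation.

    Each prototype is a sharp single-fiber ODF — a Watson angular profile
    ``exp(kappa * (u·v)^2)`` at a distinct orientation — projected onto the
    basis by least squares and normalized.  Orientations are drawn as a
    randomly rotated spherical Fibonacci set; if the separation constraint
    fails, a new rotation is tried up to ``max_tries`` times.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    eval_dirs = sphere_directions(max(4 * basis.n_coeff, 64))
    rng_seeds = np.random.SeedSequence(seed).generate_state(max_tries)
    for attempt_seed in rng_seeds:
        orientations = sphere_directions(max(k, 2), seed=int(attempt_seed % (2**31)))[:k]
        protos = np.empty((k, basis.n_coeff))
        for i, v in enumerate(orientations):
            values = np.exp(kappa * (eval_dirs @ v) ** 2)
            values /= values.max()
            c = fit_sh(values, eval_dirs, basis)
            protos[i] = c / np.linalg.norm(c)
        if k == 1:
            return protos
        d = np.linalg.norm(protos[:, None, :] - protos[None, :, :], axis=2)
        if d[np.triu_indices(k, 1)].min() >= separation:
            return protos
    raise SeparationError(
        f"could not place {k} prototypes with separation {separation} in {max_tries} tries"
    )


def template_geometry(config: SyntheticConfig) -> tuple[tuple[int, int, int], np.ndarray]:
    """Template grid: the canonical shape and centered voxel-to-world affine."""
    shape = tuple(config.grid_shape)
    vs = np.asarray(config.voxel_size_mm, dtype=float)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(vs)
    affine[:3, 3] = -vs * (np.asarray(shape) - 1) / 2.0
    return shape, affine


def _ellipsoids(config: SyntheticConfig) -> list[tuple[np.ndarray, np.ndarray]]:
    """Centers and semi-axes (mm, world) of the two thalami."""
    shape, affine = template_geometry(config)
    fov = np.asarray(config.voxel_size_mm) * np.asarray(shape)
    semi = np.minimum(np.array([9.0, 12.0, 10.0]), fov / 2.0 * 0.55)
    cx = semi[0] + 4.0  # lateral offset keeping a >= 8 mm inter-thalamic gap
    return [
        (np.array([-cx, 0.0, 0.0]), semi),
        (np.array([cx, 0.0, 0.0]), semi),
    ]


def _inside(points: np.ndarray, center: np.ndarray, semi: np.ndarray) -> np.ndarray:
    return np.sum(((points - center) / semi) ** 2, axis=1) <= 1.0


def _template_seeds(config: SyntheticConfig) -> np.ndarray:
    """(2k, 3) template-world nucleus seed points; left block then right.

    Seeds are k-means centers of the canonical ellipsoid voxel coordinates,
    sorted lexicographically so the code order is reproducible.
    """
    shape, affine = template_geometry(config)
    idx = np.indices(shape).reshape(3, -1).T
    world = voxel_to_world(affine, idx)
    k = config.k_per_hemisphere
    seeds = []
    for hemi, (center, semi) in enumerate(_ellipsoids(config)):
        pts = world[_inside(world, center, semi)]
        if len(pts) < 3 * k:
            raise SizingError(
                f"ellipsoid {hemi} holds only {len(pts)} voxels; need >= {3 * k} for k={k}"
            )
        if k == 1:
            centers = pts.mean(axis=0, keepdims=True)
        else:
            km = KMeans(n_clusters=k, n_init=4, random_state=int(config.seed % (2**31)))
            km.fit(pts)
            centers = km.cluster_centers_
        centers = centers[np.lexsort(centers.T[::-1])]
        seeds.append(centers)
    return np.vstack(seeds)


def _random_affine(rng: np.random.Generator, magnitude: float) -> np.ndarray:
    """Small rigid + isotropic-scaling world affine bounded by ``magnitude``
    (mm of translation, degrees of rotation; scale within 0.5% per unit)."""
    angles = np.deg2rad(rng.uniform(-magnitude, magnitude, size=3))
    cx, cy, cz = np.cos(angles)
    sx, sy, sz = np.sin(angles)
    rot_x = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    rot_y = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rot_z = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    scale = 1.0 + rng.uniform(-magnitude, magnitude) * 0.005
    mat = np.eye(4)
    mat[:3, :3] = scale * (rot_z @ rot_y @ rot_x)
    mat[:3, 3] = rng.uniform(-magnitude, magnitude, size=3)
    return mat


def _grow_subject_labels(
    world_template: np.ndarray,
    ellipsoids,
    seeds: np.ndarray,
    k: int,
    shape: tuple[int, int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Mask and label grid for one subject, in its own grid.

    ``world_template`` are the subject's voxel centers mapped into template
    world coordinates; labels are nearest-seed cells inside each ellipsoid.
    """
    mask = np.zeros(shape, dtype=bool).reshape(-1)
    labels = np.zeros(np.prod(shape), dtype=np.int32)
    for hemi, (center, semi) in enumerate(ellipsoids):
        inside = _inside(world_template, center, semi)
        hemi_seeds = seeds[hemi * k : (hemi + 1) * k]
        pts = world_template[inside]
        d = np.linalg.norm(pts[:, None, :] - hemi_seeds[None, :, :], axis=2)
        labels[inside] = np.argmin(d, axis=1) + 1 + hemi * k
        mask |= inside
    return mask.reshape(shape), labels.reshape(shape)


def _labels_valid(labels: np.ndarray, n_labels: int) -> bool:
    structure = np.ones((3, 3, 3), dtype=bool)
    for code in range(1, n_labels + 1):
        region = labels == code
        if not region.any():
            return False
        _, n_comp = ndimage.label(region, structure=structure)
        if n_comp != 1:
            return False
    return True


def generate_cohort(config: SyntheticConfig) -> list[SubjectBundle]:
    """Generate ``n_subjects`` reproducible synthetic subject bundles.

    Identical config (including seed) yields bit-identical cohorts: all
    randomness flows from one seed sequence, one child stream per subject.
    """
    shape, affine = template_geometry(config)
    ellipsoids = _ellipsoids(config)
    k = config.k_per_hemisphere
    n_labels = 2 * k
    basis = build_basis(config.sh_order)
    prototypes = make_cluster_prototypes(
        k, basis, config.prototype_separation, seed=int(config.seed % (2**31))
    )
    # same microstructural prototypes on both sides; codes stay distinct
    prototypes = np.vstack([prototypes, prototypes])
    seeds0 = _template_seeds(config)
    lut = default_lut(k)

    idx = np.indices(shape).reshape(3, -1).T
    world_subject = voxel_to_world(affine, idx)

    bundles = []
    for s in range(config.n_subjects):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, s]))
        to_template = _random_affine(rng, config.transform_magnitude)
        inv = np.linalg.inv(to_template)
        homo = np.c_[world_subject, np.ones(len(world_subject))]
        world_template = (homo @ to_template.T)[:, :3]

        mask = labels = None
        for _ in range(20):  # re-jitter until every nucleus is whole
            jitter = rng.normal(0.0, config.spatial_jitter_mm, size=seeds0.shape) if config.spatial_jitter_mm > 0 else 0.0
            seeds = seeds0 + jitter
            mask, labels = _grow_subject_labels(world_template, ellipsoids, seeds, k, shape)
            if _labels_valid(labels, n_labels):
                break
        else:
            raise RuntimeError("could not realize connected, non-empty nuclei; reduce jitter")

        structure = np.ones((3, 3, 3), dtype=bool)
        boundary = mask & ~ndimage.binary_erosion(mask, structure=structure)
        if config.csf_rim_width_vox > 0:
            csf_rim = mask & ~ndimage.binary_erosion(
                mask, structure=structure, iterations=config.csf_rim_width_vox
            )
        else:
            csf_rim = np.zeros(shape, dtype=bool)
        lateral_mm = ellipsoids[1][0][0]  # |x| beyond the ellipsoid centers
        fa_rim = boundary & (np.abs(world_template[:, 0]).reshape(shape) >= lateral_mm)

        csf = np.full(shape, 0.05)
        gm = np.full(shape, 0.15)
        wm = np.full(shape, 0.80)
        interior = mask & ~csf_rim
        gm[interior], wm[interior], csf[interior] = 0.88, 0.10, 0.02
        gm[csf_rim], wm[csf_rim], csf[csf_rim] = 0.50, 0.20, 0.30

        fa = np.full(shape, 0.45)
        fa[mask] = 0.25
        fa[fa_rim] = 0.70

        mask_voxels = np.argwhere(mask)
        codes = labels[tuple(mask_voxels.T)]
        proto_per_voxel = prototypes[codes - 1]
        samples = np.repeat(
            proto_per_voxel[:, None, :], config.n_bootstrap_samples, axis=1
        )
        if config.feature_noise_sd > 0:
            samples = samples + rng.normal(0.0, config.feature_noise_sd, size=samples.shape)

        truth = LabeledVolume(labels=labels, affine=affine, label_table=dict(lut.names))
        bundles.append(
            SubjectBundle(
                thalamus_mask=mask,
                gm=gm,
                wm=wm,
                csf=csf,
                fa=fa,
                mask_voxels=mask_voxels,
                odf_samples=samples,
                true_labels=truth,
                to_template=to_template,
                csf_rim=csf_rim,
                fa_rim=fa_rim,
            )
        )
    return bundles


def save_cohort(bundles: list[SubjectBundle], out_dir, k_per_hemisphere: int = 7) -> None:
    """Write a cohort in the canonical per-subject layout.

    ``<out>/lut.txt`` plus ``subjectNNN/{mask,gm,wm,csf,fa}.nii.gz``, the
    5D bootstrap stack ``odf_samples.nii.gz`` (x, y, z, sample,
    coefficient; zero off-mask), ``truth.nii.gz`` and ``to_template.txt``.
    """
    from pathlib import Path

    from .io import write_affine, write_nifti

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    default_lut(k_per_hemisphere).write(out / "lut.txt")
    for s, b in enumerate(bundles):
        d = out / f"subject{s:03d}"
        d.mkdir(exist_ok=True)
        affine = b.true_labels.affine
        write_nifti(b.thalamus_mask, affine, d / "mask.nii.gz", dtype=np.uint8)
        for name in ("gm", "wm", "csf", "fa"):
            write_nifti(getattr(b, name), affine, d / f"{name}.nii.gz")
        stack = np.zeros(b.thalamus_mask.shape + b.odf_samples.shape[1:], dtype=np.float32)
        stack[tuple(b.mask_voxels.T)] = b.odf_samples
        write_nifti(stack, affine, d / "odf_samples.nii.gz")
        write_nifti(b.true_labels.labels, affine, d / "truth.nii.gz", dtype=np.int16)
        write_affine(b.to_template, d / "to_template.txt")


def load_cohort(in_dir) -> list[SubjectBundle]:
    """Read a cohort written by :func:`save_cohort`.

    The planted-rim annotations are not stored on disk and come back as
    ``None``; everything the pipeline consumes is reconstructed exactly.
    """
    from pathlib import Path

    from .io import ColorLUT, read_affine, read_nifti

    root = Path(in_dir)
    lut = ColorLUT.read(root / "lut.txt")
    bundles = []
    for d in sorted(root.glob("subject*")):
        mask, affine = read_nifti(d / "mask.nii.gz")
        mask = mask.astype(bool)
        gm, _ = read_nifti(d / "gm.nii.gz")
        wm, _ = read_nifti(d / "wm.nii.gz")
        csf, _ = read_nifti(d / "csf.nii.gz")
        fa, _ = read_nifti(d / "fa.nii.gz")
        stack, _ = read_nifti(d / "odf_samples.nii.gz")
        truth, _ = read_nifti(d / "truth.nii.gz")
        voxels = np.argwhere(mask)
        bundles.append(
            SubjectBundle(
                thalamus_mask=mask,
                gm=gm,
                wm=wm,
                csf=csf,
                fa=fa,
                mask_voxels=voxels,
                odf_samples=stack[tuple(voxels.T)].astype(float),
                true_labels=LabeledVolume(truth.astype(np.int32), affine, dict(lut.names)),
                to_template=read_affine(d / "to_template.txt"),
            )
        )
    return bundles


def template_truth(config: SyntheticConfig) -> LabeledVolume:
    """The canonical (unjittered, identity-transform) anatomy in template space."""
    shape, affine = template_geometry(config)
    idx = np.indices(shape).reshape(3, -1).T
    world = voxel_to_world(affine, idx)
    seeds = _template_seeds(config)
    _, labels = _grow_subject_labels(world, _ellipsoids(config), seeds, config.k_per_hemisphere, shape)
    return LabeledVolume(labels=labels, affine=affine, label_table=dict(default_lut(config.k_per_hemisphere).names))
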