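"""Probabilistic atlas (SPAM) construction and application.

Per-subject parcellations are mapped to a common template grid with
nearest-neighbor interpolation (labels are categorical), per-label
proportion maps are averaged across subjects, and a discrete
maximum-likelihood atlas takes at every voxel the label with the greatest
probability, with multi-mode ties broken by a seeded uniform draw.

Template space here is defined by known affine transforms; the nonlinear
template-building step of a full study is outside this package's scope, so
"registration" is exact by construction in the synthetic pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
import re

import numpy as np
from scipy import ndimage

from .io import read_nifti, write_nifti, ColorLUT
from .types import LabeledVolume, voxel_to_world, world_to_voxel


@dataclass(frozen=True)
class AffineTransform:
    """World-mm subject -> world-mm template affine map."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("transform must be 4x4")
        if not np.allclose(m[3], [0, 0, 0, 1]):
            raise ValueError("last row must be (0, 0, 0, 1)")
        if abs(np.linalg.det(m[:3, :3])) < 1e-12:
            raise ValueError("transform must be invertible")
        object.__setattr__(self, "matrix", m)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return voxel_to_world(self.matrix, points)

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))


@dataclass
class SPAM:
    """Spatial probabilistic atlas map: 4D stack of per-label proportions.

    ``probabilities`` is (X, Y, Z, n_labels); frame order follows ``codes``
    (the LUT order).  Every value is an exact multiple of 1/n_subjects and
    per-voxel sums over labels never exceed 1.
    """

    probabilities: np.ndarray
    codes: list[int]
    names: dict[int, str]
    n_subjects: int
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.ndim != 4 or self.probabilities.shape[3] != len(self.codes):
            raise ValueError("probabilities must be (X, Y, Z, n_labels)")
        counts = self.probabilities * self.n_subjects
        if np.max(np.abs(counts - np.round(counts))) > 1e-6:
            raise ValueError("probabilities must be multiples of 1/n_subjects")
        # tolerance admits float32 storage round-trips; build_spam itself is exact
        if np.max(self.probabilities.sum(axis=3)) > 1.0 + 1e-6:
            raise ValueError("per-voxel label probabilities must sum to <= 1")


def resample_labels_nn(
    labels: LabeledVolume,
    transform: AffineTransform,
    target_shape: tuple[int, int, int],
    target_affine: np.ndarray,
) -> LabeledVolume:
    """Pull a label volume onto a target grid with nearest-neighbor lookup.

    Each target voxel center is mapped back through the inverse transform
    and takes the label of the nearest source voxel; labels outside the
    source field of view become background.
    """
    inv = np.linalg.inv(transform.matrix)
    idx = np.indices(target_shape).reshape(3, -1).T
    world_t = voxel_to_world(target_affine, idx)
    world_s = voxel_to_world(inv, world_t)
    vox_s = np.rint(world_to_voxel(labels.affine, world_s)).astype(int)
    inside = np.all((vox_s >= 0) & (vox_s < labels.labels.shape), axis=1)
    out = np.zeros(target_shape, dtype=labels.labels.dtype).reshape(-1)
    out[inside] = labels.labels[tuple(vox_s[inside].T)]
    table = {c: labels.label_table[c] for c in set(np.unique(out)) - {0}}
    return LabeledVolume(labels=out.reshape(target_shape), affine=np.asarray(target_affine, float), label_table=table)


def build_spam(warped: list[LabeledVolume], codes: list[int] | None = None) -> SPAM:
    """Average warped label volumes into per-label proportion maps.

    ``P_l(v)`` is the fraction of subjects carrying label ``l`` at template
    voxel ``v``.  Background is excluded from the frame list.
    """
    if not warped:
        raise ValueError("need at least one warped volume")
    shape = warped[0].labels.shape
    affine = warped[0].affine
    names: dict[int, str] = {}
    for w in warped:
        if w.labels.shape != shape:
            raise ValueError("all warped volumes must share the template grid")
        names.update(w.label_table)
    if codes is None:
        codes = sorted(names)
    n = len(warped)
    probs = np.zeros(shape + (len(codes),), dtype=float)
    for w in warped:
        for j, code in enumerate(codes):
            probs[..., j] += w.labels == code
    probs /= n
    return SPAM(
        probabilities=probs,
        codes=list(codes),
        names={c: names.get(c, f"label{c}") for c in codes},
        n_subjects=n,
        affine=affine,
    )


def _argmax_with_ties(probs2d: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Row-wise argmax column index; multi-mode rows draw uniformly from the
    tied columns, consuming the RNG in row (raster) order."""
    best = probs2d.max(axis=1)
    out = np.argmax(probs2d, axis=1)
    tied = (probs2d == best[:, None]).sum(axis=1) > 1
    for i in np.flatnonzero(tied):
        modes = np.flatnonzero(probs2d[i] == best[i])
        out[i] = modes[rng.integers(len(modes))]
    return out


def max_likelihood_atlas(spam: SPAM, seed: int = 0) -> LabeledVolume:
    """Discrete atlas: per voxel, the label with the highest SPAM value.

    Voxels where every label probability is zero stay background; ties are
    resolved by a seeded uniform draw over the modes (one RNG stream,
    voxels visited in raster-scan order), so a fixed seed fixes the volume.
    """
    flat = spam.probabilities.reshape(-1, len(spam.codes))
    support = flat.max(axis=1) > 0
    rng = np.random.default_rng(seed)
    out = np.zeros(flat.shape[0], dtype=np.int32)
    codes = np.asarray(spam.codes, dtype=np.int32)
    out[support] = codes[_argmax_with_ties(flat[support], rng)]
    labels = out.reshape(spam.probabilities.shape[:3])
    table = {c: spam.names[c] for c in set(np.unique(labels)) - {0}}
    return LabeledVolume(labels=labels, affine=spam.affine, label_table=table)


def segment_with_atlas(
    spam: SPAM,
    to_template: AffineTransform,
    subject_mask: np.ndarray,
    subject_affine: np.ndarray,
    seed: int = 0,
    discrete_warp: bool = False,
) -> LabeledVolume:
    """Atlas-based segmentation of a subject's thalamic mask.

    The probability frames are warped to subject space through the inverse
    transform (nearest-neighbor on each frame) and every mask voxel takes
    the argmax label, seeded tie-break as in :func:`max_likelihood_atlas`.
    Mask voxels with zero warped probability inherit the label of the
    nearest labeled voxel inside the mask, so the mask is covered
    completely.  ``discrete_warp=True`` instead warps the precomputed
    maximum-likelihood volume directly.
    """
    subject_mask = np.asarray(subject_mask).astype(bool)
    if not subject_mask.any():
        raise ValueError("subject mask is empty")
    mask_idx = np.argwhere(subject_mask)
    world_s = voxel_to_world(subject_affine, mask_idx)
    world_t = to_template.apply(world_s)
    vox_t = np.rint(world_to_voxel(spam.affine, world_t)).astype(int)
    shape_t = spam.probabilities.shape[:3]
    inside = np.all((vox_t >= 0) & (vox_t < shape_t), axis=1)

    labels_flat = np.zeros(len(mask_idx), dtype=np.int32)
    rng = np.random.default_rng(seed)
    if discrete_warp:
        ml = max_likelihood_atlas(spam, seed=seed)
        labels_flat[inside] = ml.labels[tuple(vox_t[inside].T)]
    else:
        probs = np.zeros((len(mask_idx), len(spam.codes)))
        probs[inside] = spam.probabilities[tuple(vox_t[inside].T)]
        support = probs.max(axis=1) > 0
        codes = np.asarray(spam.codes, dtype=np.int32)
        labels_flat[support] = codes[_argmax_with_ties(probs[support], rng)]

    out = np.zeros(subject_mask.shape, dtype=np.int32)
    out[tuple(mask_idx.T)] = labels_flat
    unlabeled = subject_mask & (out == 0)
    if unlabeled.any():
        has_label = out > 0
        if not has_label.any():
            raise ValueError("atlas support does not intersect the subject mask")
        voxel_size = np.linalg.norm(np.asarray(subject_affine)[:3, :3], axis=0)
        _, nearest = ndimage.distance_transform_edt(
            ~has_label, sampling=voxel_size, return_indices=True
        )
        out[unlabeled] = out[tuple(ind[unlabeled] for ind in nearest)]
    table = {c: spam.names[c] for c in set(np.unique(out)) - {0}}
    return LabeledVolume(labels=out, affine=np.asarray(subject_affine, float), label_table=table)


_DESCRIP_RE = re.compile(r"SPAM;N=(\d+)")


def write_spam(spam: SPAM, path) -> None:
    """Write the 4D probability stack (frame order = LUT order) as float32."""
    write_nifti(
        spam.probabilities,
        spam.affine,
        path,
        dtype=np.float32,
        descrip=f"SPAM;N={spam.n_subjects}",
    )


def read_spam(path, lut: ColorLUT) -> SPAM:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    descrip = img.header["descrip"].tobytes().decode(errors="ignore")
    m = _DESCRIP_RE.search(descrip)
    n_subjects = int(m.group(1)) if m else 1
    codes = lut.codes[: data.shape[3]]
    return SPAM(
        probabilities=data,
        codes=codes,
        names={c: lut.names[c] for c in codes},
        n_subjects=n_subjects,
        affine=np.asarray(img.affine, dtype=float),
    )


def write_maxlik(volume: LabeledVolume, path) -> None:
    write_nifti(volume.labels, volume.affine, path, dtype=np.int16)


def read_maxlik(path, lut: ColorLUT) -> LabeledVolume:
    data, affine = read_nifti(path)
    data = data.astype(np.int32)
    table = {c: lut.names[c] for c in set(np.unique(data)) - {0}}
    return LabeledVolume(labels=data, affine=affine, label_table=table)
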