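"""Refinement of the whole-thalamus mask.

FreeSurfer-style thalamic masks leak into neighbouring structures.  Two
partial-volume contaminations are removed before parcellation: voxels with
more than 5% CSF probability (ventricle border) and voxels with fractional
anisotropy above 0.55, which are more plausibly internal capsule than
thalamus.  Both thresholds are strict: a voxel exactly at the threshold is
kept.  No morphological cleanup is applied afterwards.

The pipeline normally consumes a precomputed FA map; ``fit_tensor_loglinear``
and ``compute_fa`` are provided to derive one from single-shell
diffusion-weighted attenuations when needed.  All inputs are assumed
co-registered on one voxel grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class RefinementConfig:
    """Exclusion thresholds: CSF probability and fractional anisotropy."""

    csf_threshold: float = 0.05
    fa_threshold: float = 0.55

    def __post_init__(self) -> None:
        for name, v in (("csf_threshold", self.csf_threshold), ("fa_threshold", self.fa_threshold)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class TensorFit:
    """Diffusion-tensor eigendecomposition: eigenvalues sorted descending."""

    eigenvalues: np.ndarray  # (3,) descending, clamped at 0
    eigenvectors: np.ndarray  # (3, 3), columns match eigenvalues


def compute_fa(eigenvalues) -> float:
    """Fractional anisotropy of a diffusion tensor from its eigenvalues.

    FA = sqrt(3/2) * sqrt(sum((l_i - mean)^2)) / sqrt(sum(l_i^2)), in [0, 1].
    An all-zero tensor returns 0 by convention.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.shape != (3,):
        raise ValueError("expected three eigenvalues")
    if np.any(lam < 0):
        raise ValueError("eigenvalues must be non-negative")
    denom = np.sqrt(np.sum(lam**2))
    if denom == 0.0:
        return 0.0
    num = np.sqrt(np.sum((lam - lam.mean()) ** 2))
    return float(min(1.0, np.sqrt(1.5) * num / denom))


def refine_mask(
    mask: np.ndarray,
    csf_prob: np.ndarray,
    fa: np.ndarray,
    cfg: RefinementConfig = RefinementConfig(),
) -> np.ndarray:
    """Remove CSF-contaminated and internal-capsule-like voxels from a mask.

    Returns ``mask AND csf_prob <= csf_threshold AND fa <= fa_threshold``;
    always a subset of the input mask.
    """
    mask = np.asarray(mask).astype(bool)
    csf_prob = np.asarray(csf_prob, dtype=float)
    fa = np.asarray(fa, dtype=float)
    if not (mask.shape == csf_prob.shape == fa.shape):
        raise ValueError("mask, csf_prob and fa must share one grid")
    return mask & (csf_prob <= cfg.csf_threshold) & (fa <= cfg.fa_threshold)


def fit_tensor_loglinear(signals: np.ndarray, bvals: np.ndarray, bvecs: np.ndarray) -> TensorFit:
    """Ordinary least-squares diffusion-tensor fit on log-attenuations.

    ``signals`` are positive per-volume measurements; ``bvals`` in s/mm^2
    (zeros mark b0 volumes); ``bvecs`` unit gradient directions, (N, 3).
    Requires at least six non-collinear directions and one b0.
    """
    signals = np.asarray(signals, dtype=float)
    bvals = np.asarray(bvals, dtype=float)
    bvecs = np.asarray(bvecs, dtype=float)
    if np.any(signals <= 0):
        raise ValueError("signals must be positive")
    if signals.shape[0] != bvals.shape[0] or bvecs.shape != (bvals.shape[0], 3):
        raise ValueError("signals, bvals and bvecs must align")
    g = bvecs
    # log S = log S0 - b * g^T D g; unknowns [log S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz]
    design = np.column_stack(
        [
            np.ones_like(bvals),
            -bvals * g[:, 0] ** 2,
            -bvals * g[:, 1] ** 2,
            -bvals * g[:, 2] ** 2,
            -2 * bvals * g[:, 0] * g[:, 1],
            -2 * bvals * g[:, 0] * g[:, 2],
            -2 * bvals * g[:, 1] * g[:, 2],
        ]
    )
    if np.linalg.matrix_rank(design) < 7:
        raise ValueError("rank-deficient design: need >= 6 non-collinear directions and a b0")
    beta, *_ = np.linalg.lstsq(design, np.log(signals), rcond=None)
    dxx, dyy, dzz, dxy, dxz, dyz = beta[1:]
    tensor = np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])
    w, v = np.linalg.eigh(tensor)
    order = np.argsort(w)[::-1]
    return TensorFit(eigenvalues=np.maximum(w[order], 0.0), eigenvectors=v[:, order])
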