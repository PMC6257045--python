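"""Per-voxel ODF feature fields for the clustering stage.

The clustering feature of each voxel is the arithmetic mean, across residual
bootstrap samples, of its ODF SH-coefficient vector; before entering the
k-means metric the coefficients are multiplied by a fixed scale factor
(default 100) so feature distances land in the same numeric range as spatial
distances in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ODFFeatureField:
    """SH coefficients restricted to an ordered list of mask voxels.

    ``voxels`` is (N, 3) integer voxel coordinates; ``coefficients`` is
    (N, n_coeff) and rows align one-to-one with ``voxels``.
    """

    voxels: np.ndarray
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.voxels.ndim != 2 or self.voxels.shape[1] != 3:
            raise ValueError("voxels must be (N, 3)")
        if self.coefficients.ndim != 2 or len(self.coefficients) != len(self.voxels):
            raise ValueError("coefficients rows must align with voxels")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("coefficients contain non-finite values")

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)

    @property
    def n_coeff(self) -> int:
        return self.coefficients.shape[1]


def mean_bootstrap_coefficients(samples: np.ndarray, voxels: np.ndarray) -> ODFFeatureField:
    """Average a bootstrap stack into the per-voxel mean-coefficient field.

    ``samples`` has shape (n_voxels, n_samples, n_coeff) — one stack of
    bootstrap ODF coefficient vectors per mask voxel.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 3:
        raise ValueError("samples must be (n_voxels, n_samples, n_coeff)")
    if samples.shape[1] < 1:
        raise ValueError("need at least one bootstrap sample")
    return ODFFeatureField(voxels=voxels, coefficients=samples.mean(axis=1))


def scale_features(field: ODFFeatureField, scale: float) -> ODFFeatureField:
    """Multiply every coefficient by ``scale`` (> 0); distances scale alike."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    return ODFFeatureField(voxels=field.voxels, coefficients=field.coefficients * scale)
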