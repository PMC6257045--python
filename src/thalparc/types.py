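"""Core containers shared by the parcellation and atlas modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class LabeledVolume:
    """A discrete label grid with world geometry.

    Parameters
    ----------
    labels
        3D integer array; 0 is background.
    affine
        4x4 voxel-to-world matrix (mm).  Must be invertible.
    label_table
        Mapping from nonzero label code to region name.  Every nonzero
        code present in ``labels`` must have an entry.
    """

    labels: np.ndarray
    affine: np.ndarray
    label_table: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.label_table)
        if missing:
            raise ValueError(f"label codes without a table entry: {sorted(missing)}")

    @property
    def codes(self) -> list[int]:
        """Sorted nonzero label codes present in the grid."""
        return sorted(set(np.unique(self.labels)) - {0})

    def voxels_of(self, code: int) -> np.ndarray:
        """(N, 3) voxel indices carrying ``code``."""
        return np.argwhere(self.labels == code)

    def world_coords(self, voxels: np.ndarray) -> np.ndarray:
        """Map (N, 3) voxel indices to world-mm coordinates of voxel centers."""
        voxels = np.atleast_2d(voxels)
        homo = np.c_[voxels, np.ones(len(voxels))]
        return (homo @ self.affine.T)[:, :3]


def voxel_to_world(affine: np.ndarray, voxels: np.ndarray) -> np.ndarray:
    """Apply a 4x4 voxel-to-world affine to (N, 3) voxel indices."""
    voxels = np.atleast_2d(np.asarray(voxels, dtype=float))
    homo = np.c_[voxels, np.ones(len(voxels))]
    return (homo @ np.asarray(affine).T)[:, :3]


def world_to_voxel(affine: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Map (N, 3) world-mm points back to (fractional) voxel indices."""
    return voxel_to_world(np.linalg.inv(affine), points)
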