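"""NIfTI, transform-matrix and color-LUT input/output.

All volumes travel as NIfTI-1 (.nii or .nii.gz) through nibabel.  Affine
subject-to-template transforms are stored as plain 4x4 whitespace matrices.
Color lookup tables use the FreeSurfer text layout
(``code name R G B opacity``), one record per line, ``#`` comments allowed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np


def read_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI file; return ``(data, affine)``.

    4D/5D stacks are returned as-is (last axes are frame axes).
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # malformed header, wrong magic, truncation
        raise ValueError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    return data, np.asarray(img.affine, dtype=float)


def write_nifti(data: np.ndarray, affine: np.ndarray, path, dtype=None, descrip: str | None = None) -> None:
    """Write an array with a voxel-to-world affine as NIfTI-1."""
    data = np.asarray(data)
    if dtype is not None:
        data = data.astype(dtype)
    elif data.dtype == np.float64:
        data = data.astype(np.float32)
    elif data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, np.asarray(affine, dtype=float))
    if descrip is not None:
        img.header["descrip"] = descrip.encode()[:79]
    img.to_filename(str(path))


def read_affine(path) -> np.ndarray:
    """Read a 4x4 whitespace-delimited transform matrix."""
    mat = np.loadtxt(str(path))
    if mat.shape != (4, 4):
        raise ValueError(f"{path}: expected a 4x4 matrix, got {mat.shape}")
    return mat


def write_affine(matrix: np.ndarray, path) -> None:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (4, 4):
        raise ValueError("transform must be 4x4")
    np.savetxt(str(path), matrix, fmt="%.10g")


@dataclass
class ColorLUT:
    """FreeSurfer-style color lookup table.

    ``records`` maps label code -> (name, R, G, B, opacity); channel values
    are 8-bit integers.  Codes and names must be unique.
    """

    records: dict[int, tuple[str, int, int, int, int]]

    def __post_init__(self) -> None:
        names = [r[0] for r in self.records.values()]
        if len(set(names)) != len(names):
            raise ValueError("LUT names must be unique")
        for code, (name, *rgba) in self.records.items():
            if not all(0 <= v <= 255 for v in rgba):
                raise ValueError(f"LUT channels out of [0, 255] for code {code}")

    @property
    def codes(self) -> list[int]:
        """Label codes in file (insertion) order — the canonical frame order."""
        return list(self.records)

    @property
    def names(self) -> dict[int, str]:
        return {code: rec[0] for code, rec in self.records.items()}

    def write(self, path) -> None:
        lines = ["# code name R G B opacity"]
        for code, (name, r, g, b, a) in self.records.items():
            lines.append(f"{code:4d}  {name:<14s} {r:3d} {g:3d} {b:3d} {a:3d}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read(cls, path) -> "ColorLUT":
        records: dict[int, tuple[str, int, int, int, int]] = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 6:
                raise ValueError(f"malformed LUT line: {raw!r}")
            code = int(parts[0])
            if code in records:
                raise ValueError(f"duplicate LUT code {code}")
            records[code] = (parts[1], int(parts[2]), int(parts[3]), int(parts[4]), int(parts[5]))
        return cls(records)
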