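"""Real symmetric spherical-harmonic (SH) basis for ODF representation.

Antipodally symmetric ODFs are expanded in the real, even-degree SH basis
standard in diffusion MRI.  Coefficients are indexed lexicographically in
``(l, m)`` with ``l`` even and ``-l <= m <= l``; order ``L`` therefore gives
``(L + 1)(L + 2) / 2`` coefficients (order 6 -> 28).

The real basis is built from the complex harmonics ``Y_l^m`` as

* ``m < 0``:  ``sqrt(2) * (-1)^m * Im(Y_l^|m|)``
* ``m = 0``:  ``Y_l^0`` (real)
* ``m > 0``:  ``sqrt(2) * (-1)^m * Re(Y_l^m)``

which is orthonormal on the sphere; the ``l = 0`` function is the constant
``1 / sqrt(4*pi)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import sph_harm_y


@dataclass(frozen=True)
class SHBasis:
    """Real symmetric SH basis of even maximum order ``order``."""

    order: int
    lm: tuple[tuple[int, int], ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.order < 0 or self.order % 2 != 0:
            raise ValueError("SH order must be an even non-negative integer")
        lm = tuple((l, m) for l in range(0, self.order + 1, 2) for m in range(-l, l + 1))
        object.__setattr__(self, "lm", lm)

    @property
    def n_coeff(self) -> int:
        return (self.order + 1) * (self.order + 2) // 2


def build_basis(order: int) -> SHBasis:
    """Construct the even-order real symmetric basis; order 6 has 28 terms."""
    return SHBasis(order=order)


def _check_unit(directions: np.ndarray) -> np.ndarray:
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    if directions.shape[1] != 3:
        raise ValueError("directions must be (N, 3)")
    norms = np.linalg.norm(directions, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ValueError("directions must be unit vectors")
    return directions


def basis_matrix(basis: SHBasis, directions: np.ndarray) -> np.ndarray:
    """Design matrix B with ``B[i, j] = Y_j(direction_i)``."""
    directions = _check_unit(directions)
    x, y, z = directions.T
    theta = np.arccos(np.clip(z, -1.0, 1.0))  # polar angle
    phi = np.arctan2(y, x)
    cols = []
    for l, m in basis.lm:
        ylm = sph_harm_y(l, abs(m), theta, phi)
        if m < 0:
            cols.append(np.sqrt(2.0) * (-1.0) ** m * ylm.imag)
        elif m == 0:
            cols.append(ylm.real)
        else:
            cols.append(np.sqrt(2.0) * (-1.0) ** m * ylm.real)
    return np.column_stack(cols)


def evaluate_sh(coeffs: np.ndarray, directions: np.ndarray, basis: SHBasis) -> np.ndarray:
    """Evaluate the SH expansion at unit ``directions``.

    Linear in ``coeffs``; even-degree-only terms make the result antipodally
    symmetric by construction.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.shape[-1] != basis.n_coeff:
        raise ValueError(f"expected {basis.n_coeff} coefficients, got {coeffs.shape[-1]}")
    return basis_matrix(basis, directions) @ coeffs


def fit_sh(
    values: np.ndarray,
    directions: np.ndarray,
    basis: SHBasis,
    regularization: float = 0.0,
) -> np.ndarray:
    """Least-squares projection of sampled function values onto the basis.

    With ``regularization > 0`` a Laplace-Beltrami ridge penalty
    ``lambda * (l(l+1))^2`` is added, shrinking high-degree terms.
    """
    if regularization < 0:
        raise ValueError("regularization must be non-negative")
    values = np.asarray(values, dtype=float)
    B = basis_matrix(basis, directions)
    if regularization == 0.0:
        if B.shape[0] < basis.n_coeff or np.linalg.matrix_rank(B) < basis.n_coeff:
            raise ValueError(
                "underdetermined SH fit: need >= n_coeff well-spread directions "
                "or a positive regularization"
            )
        coeffs, *_ = np.linalg.lstsq(B, values, rcond=None)
        return coeffs
    lb = np.array([(l * (l + 1)) ** 2 for l, _ in basis.lm], dtype=float)
    lhs = B.T @ B + regularization * np.diag(lb)
    return np.linalg.solve(lhs, B.T @ values)


def sphere_directions(n: int, seed: int | None = None) -> np.ndarray:
    """``n`` well-spread unit vectors (spherical Fibonacci lattice).

    An optional seeded random rotation decorrelates the lattice from the
    coordinate axes.
    """
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    if seed is not None:
        rng = np.random.default_rng(seed)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        dirs = dirs @ q.T
    return dirs
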