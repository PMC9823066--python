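"""Shared small numerics: half-vectorization order and seeding helpers.

The half-vectorization ("vech") order used throughout the package for the
unique elements of a symmetric k x k matrix is row-wise upper triangle:
(0,0), (0,1), ..., (0,k-1), (1,1), (1,2), ..., (k-1,k-1).
The sampling covariance V of a genetic covariance matrix S and the free
parameter vector of the latent model both follow this order.
"""

from __future__ import annotations

import numpy as np


def vech_indices(k: int) -> list[tuple[int, int]]:
    """Row-wise upper-triangle index pairs of a k x k symmetric matrix."""
    return [(i, j) for i in range(k) for j in range(i, k)]


def vech(mat: np.ndarray) -> np.ndarray:
    """Half-vectorize a symmetric matrix (row-wise upper triangle)."""
    mat = np.asarray(mat, dtype=float)
    k = mat.shape[0]
    return np.array([mat[i, j] for i, j in vech_indices(k)])


def unvech(v: np.ndarray) -> np.ndarray:
    """Inverse of :func:`vech`: rebuild the symmetric matrix."""
    v = np.asarray(v, dtype=float)
    # k(k+1)/2 = len(v)
    k = int((np.sqrt(8 * len(v) + 1) - 1) / 2)
    if k * (k + 1) // 2 != len(v):
        raise ValueError(f"length {len(v)} is not a triangular number")
    out = np.zeros((k, k))
    for val, (i, j) in zip(v, vech_indices(k)):
        out[i, j] = out[j, i] = val
    return out


def check_psd(mat: np.ndarray, name: str = "matrix", tol: float = 1e-10) -> None:
    """Raise ValueError naming the offending eigenvalue if not PSD."""
    mat = np.asarray(mat, dtype=float)
    if not np.allclose(mat, mat.T, atol=1e-8):
        raise ValueError(f"{name} is not symmetric")
    w = np.linalg.eigvalsh(mat)
    if w.min() < -tol * max(1.0, abs(w).max()):
        raise ValueError(
            f"{name} is not positive semidefinite: smallest eigenvalue {w.min():.6g}"
        )


def spawn_rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic child generator for a (seed, stage...) key."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))
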