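"""Singular Spectrum Analysis: embedding, eigendecomposition, reconstruction.

SSA decomposes a scalar series by eigenanalysis of the lag-covariance matrix
R = X X^T of its Hankel trajectory matrix X.  Retaining the leading l
components and diagonally averaging the corresponding rank-restricted matrix
gives a signal reconstruction z_t; the remainder is the residual e_t with
z + e equal to the original series exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.linalg import eigh

__all__ = [
    "SSADecomposition",
    "embed",
    "decompose",
    "select_components",
    "reconstruct",
    "ssa_decompose",
]


def embed(series: np.ndarray, M: int) -> np.ndarray:
    """Hankel trajectory matrix: column j is the M-lagged window x[j:j+M].

    Shape (M, T - M + 1); requires 2 <= M <= T/2.
    """
    x = np.asarray(series, dtype=float)
    T = x.size
    if not 2 <= M <= T // 2:
        raise ValueError(f"embedding window M={M} outside [2, T/2] for T={T}")
    return sliding_window_view(x, M).T.copy()


def decompose(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigendecomposition of the lag-covariance matrix R = X X^T.

    Returns (eigenvalues, eigenvectors, principal_components) with
    eigenvalues clipped at zero and sorted nonincreasing, eigenvectors
    orthonormal in the columns, and principal components U^T X.
    """
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ValueError("empty trajectory matrix")
    R = X @ X.T
    evals, evecs = eigh(R)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    return evals, evecs, evecs.T @ X


def select_components(
    eigenvalues: np.ndarray,
    l: int | None = None,
    variance_fraction: float | None = None,
) -> np.ndarray:
    """Indices of retained components: first l, or smallest l reaching the
    cumulative variance fraction."""
    eigenvalues = np.asarray(eigenvalues, dtype=float)
    M = eigenvalues.size
    if (l is None) == (variance_fraction is None):
        raise ValueError("give exactly one of l or variance_fraction")
    if l is not None:
        if not 1 <= l <= M:
            raise ValueError(f"l={l} outside [1, {M}]")
        return np.arange(l)
    if not 0 < variance_fraction < 1:
        raise ValueError("variance_fraction must be in (0, 1)")
    total = eigenvalues.sum()
    if total == 0:
        return np.arange(1)
    share = np.cumsum(eigenvalues) / total
    return np.arange(int(np.searchsorted(share, variance_fraction - 1e-12) + 1))


def reconstruct(X_I: np.ndarray) -> np.ndarray:
    """Diagonal averaging: mean over each anti-diagonal gives a length-T series."""
    X_I = np.asarray(X_I, dtype=float)
    M, K = X_I.shape
    T = M + K - 1
    out = np.zeros(T)
    counts = np.zeros(T)
    # anti-diagonal s = i + j holds sample x[s]
    flipped = X_I[::-1]
    for s in range(T):
        d = np.diagonal(flipped, offset=s - (M - 1))
        out[s] = d.sum()
        counts[s] = d.size
    return out / counts


@dataclass
class SSADecomposition:
    """Signal/noise split of one series via SSA."""

    M: int
    X: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    I: np.ndarray
    z: np.ndarray
    residual: np.ndarray

    @property
    def l(self) -> int:
        return int(self.I.size)


def ssa_decompose(
    series: np.ndarray,
    M: int,
    l: int | None = None,
    variance_fraction: float | None = 0.95,
) -> SSADecomposition:
    """Full SSA pass: embed, decompose, group, diagonally average.

    By default components are grouped by the smallest l explaining 95% of the
    eigenvalue mass.  ``z + residual`` equals the input series exactly.
    """
    x = np.asarray(series, dtype=float)
    X = embed(x, M)
    evals, evecs, _ = decompose(X)
    if l is not None:
        variance_fraction = None
    I = select_components(evals, l=l, variance_fraction=variance_fraction)
    U = evecs[:, I]
    X_I = U @ (U.T @ X)
    z = reconstruct(X_I)
    return SSADecomposition(
        M=M, X=X, eigenvalues=evals, eigenvectors=evecs, I=I, z=z, residual=x - z
    )
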