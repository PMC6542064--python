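"""Independent reference implementations used only to check the package.

These deliberately share no code with tvgranger: the LASSO oracle is a
plain coordinate-wise soft-threshold fixed-point iteration, and the SSA
helpers are naive loop implementations of the definitions.
"""

from __future__ import annotations

import numpy as np


def soft_threshold_lasso(
    phi: np.ndarray,
    y: np.ndarray,
    lam: float,
    tol: float = 1e-10,
    max_iter: int = 200_000,
) -> np.ndarray:
    """Solve min 1/2 ||y - phi x||^2 + lam * ||x[1:]||_1 by cyclic coordinate
    descent with an unpenalized first (intercept) column."""
    n, p = phi.shape
    x = np.zeros(p)
    col_sq = np.einsum("ij,ij->j", phi, phi)
    r = y - phi @ x
    for _ in range(max_iter):
        delta = 0.0
        for j in range(p):
            if col_sq[j] == 0:
                continue
            rho = phi[:, j] @ r + col_sq[j] * x[j]
            if j == 0:
                new = rho / col_sq[j]
            else:
                new = np.sign(rho) * max(abs(rho) - lam, 0.0) / col_sq[j]
            if new != x[j]:
                r = r + phi[:, j] * (x[j] - new)
                delta = max(delta, abs(new - x[j]))
                x[j] = new
        if delta < tol:
            break
    return x


def naive_hankel(series: np.ndarray, M: int) -> np.ndarray:
    T = len(series)
    out = np.empty((M, T - M + 1))
    for i in range(M):
        for j in range(T - M + 1):
            out[i, j] = series[i + j]
    return out


def naive_diagonal_average(X: np.ndarray) -> np.ndarray:
    M, K = X.shape
    T = M + K - 1
    out = np.zeros(T)
    for s in range(T):
        vals = [X[i, s - i] for i in range(M) if 0 <= s - i < K]
        out[s] = np.mean(vals)
    return out
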