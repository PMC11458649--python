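"""Cyclic coordinate-descent kernel for the elastic-net objective.

Operates on sufficient statistics of the *standardized* design: the Gram
matrix G = XᵀX/N and the covariance vector c = Xᵀy/N. Each coordinate update
is the soft-thresholded univariate minimizer

    β_j ← S(c_j − Σ_{k≠j} G_jk β_k, λα) / (G_jj + λ(1−α)),

applied in fixed column order, which makes every fit bit-reproducible and the
objective non-increasing sweep over sweep. The kernel is JIT-compiled with
numba when available; the pure-NumPy fallback runs the same floating-point
operations in the same order.
"""

from __future__ import annotations

import numpy as np


def _cd_gram(
    G: np.ndarray,
    c: np.ndarray,
    beta: np.ndarray,
    lam1: float,
    lam2: float,
    tol: float,
    max_iter: int,
) -> tuple[int, bool]:
    """Run coordinate descent in place on ``beta``; return (sweeps, converged)."""
    p = beta.shape[0]
    for it in range(max_iter):
        max_delta = 0.0
        for j in range(p):
            bj_old = beta[j]
            # partial residual correlation with column j
            rho = c[j] - np.dot(G[j], beta) + G[j, j] * bj_old
            z = abs(rho) - lam1
            if z <= 0.0:
                bj = 0.0
            else:
                bj = (z if rho > 0.0 else -z) / (G[j, j] + lam2)
            beta[j] = bj
            d = abs(bj - bj_old)
            if d > max_delta:
                max_delta = d
        if max_delta < tol:
            return it + 1, True
    return max_iter, False


try:  # pragma: no cover - exercised implicitly wherever numba is installed
    from numba import njit

    _cd_gram = njit(cache=False)(_cd_gram)
except ImportError:  # pragma: no cover
    pass
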