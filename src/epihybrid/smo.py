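"""Sequential minimal optimization for the Gaussian-kernel SVM dual.

Simplified SMO (Platt-style): sweep candidate first multipliers, pick the
second at random among the rest, solve the two-variable subproblem in
closed form, clip to the box [0, C], and maintain a full error cache so
each update costs O(n). Training runs in double precision; the caller
rounds the retained support-vector coefficients to float32 at bundle
export.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import TrainingError

__all__ = ["SMOResult", "smo_train", "rbf_kernel_matrix", "median_sq_distance"]


@dataclass
class SMOResult:
    """Dual solution: multipliers alpha >= 0, intercept b (decision is
    sum_i alpha_i y_i K(x, x_i) + b), and convergence diagnostics."""

    alpha: np.ndarray
    b: float
    n_passes: int
    n_updates: int
    converged: bool


def rbf_kernel_matrix(X: np.ndarray, gamma: float, Z: np.ndarray | None = None) -> np.ndarray:
    """Dense Gaussian kernel matrix exp(-gamma * ||x - z||^2), double."""
    X = np.asarray(X, dtype=np.float64)
    Z = X if Z is None else np.asarray(Z, dtype=np.float64)
    sq = (
        np.sum(X * X, axis=1)[:, None]
        + np.sum(Z * Z, axis=1)[None, :]
        - 2.0 * X @ Z.T
    )
    np.maximum(sq, 0.0, out=sq)
    return np.exp(-gamma * sq)


def median_sq_distance(X: np.ndarray, rng: np.random.Generator, max_pairs: int = 20000) -> float:
    """Median pairwise squared distance (bandwidth heuristic), subsampled
    for large n."""
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    if n < 2:
        raise TrainingError("need at least two samples for the bandwidth heuristic")
    i = rng.integers(0, n, size=max_pairs)
    j = rng.integers(0, n, size=max_pairs)
    keep = i != j
    d = X[i[keep]] - X[j[keep]]
    sq = np.sum(d * d, axis=1)
    med = float(np.median(sq))
    if med <= 0:
        raise TrainingError("degenerate features: median pairwise distance is zero")
    return med


def smo_train(
    K: np.ndarray,
    y: np.ndarray,
    C: float = 10.0,
    tol: float = 1e-3,
    max_passes: int = 10,
    seed: int = 0,
    max_total_passes: int = 300,
) -> SMOResult:
    """Solve the soft-margin dual given a precomputed kernel matrix.

    ``y`` must be +/-1. Terminates when ``max_passes`` consecutive sweeps
    make no update (converged) or after ``max_total_passes`` sweeps.
    """
    K = np.asarray(K, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = y.size
    if K.shape != (n, n):
        raise TrainingError(f"kernel matrix {K.shape} does not match {n} labels")
    if not np.all(np.isin(y, (-1.0, 1.0))):
        raise TrainingError("labels must be +/-1")
    if len(np.unique(y)) < 2:
        raise TrainingError("SMO requires both classes present")

    rng = np.random.default_rng(seed)
    alpha = np.zeros(n)
    b = 0.0
    # error cache: E_i = f(x_i) - y_i with f = K @ (alpha*y) + b
    f = np.zeros(n)

    passes = 0
    total_passes = 0
    n_updates = 0
    while passes < max_passes and total_passes < max_total_passes:
        changed = 0
        for i in range(n):
            Ei = f[i] + b - y[i]
            if not (
                (y[i] * Ei < -tol and alpha[i] < C)
                or (y[i] * Ei > tol and alpha[i] > 0)
            ):
                continue
            j = int(rng.integers(0, n - 1))
            if j >= i:
                j += 1
            Ej = f[j] + b - y[j]
            ai_old, aj_old = alpha[i], alpha[j]
            if y[i] != y[j]:
                L = max(0.0, aj_old - ai_old)
                H = min(C, C + aj_old - ai_old)
            else:
                L = max(0.0, ai_old + aj_old - C)
                H = min(C, ai_old + aj_old)
            if L >= H:
                continue
            eta = 2.0 * K[i, j] - K[i, i] - K[j, j]
            if eta >= 0:
                continue
            aj = aj_old - y[j] * (Ei - Ej) / eta
            aj = min(H, max(L, aj))
            if abs(aj - aj_old) < 1e-7:
                continue
            ai = ai_old + y[i] * y[j] * (aj_old - aj)

            # intercept update (Platt's rules)
            b1 = b - Ei - y[i] * (ai - ai_old) * K[i, i] - y[j] * (aj - aj_old) * K[i, j]
            b2 = b - Ej - y[i] * (ai - ai_old) * K[i, j] - y[j] * (aj - aj_old) * K[j, j]
            if 0 < ai < C:
                b = b1
            elif 0 < aj < C:
                b = b2
            else:
                b = 0.5 * (b1 + b2)

            f += y[i] * (ai - ai_old) * K[i] + y[j] * (aj - aj_old) * K[j]
            alpha[i], alpha[j] = ai, aj
            changed += 1
            n_updates += 1
        total_passes += 1
        passes = passes + 1 if changed == 0 else 0

    return SMOResult(
        alpha=alpha,
        b=b,
        n_passes=total_passes,
        n_updates=n_updates,
        converged=passes >= max_passes,
    )
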