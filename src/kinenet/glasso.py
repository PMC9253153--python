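"""Sparse inverse-covariance estimation by the graphical lasso.

Block coordinate-descent solver for

    max_{Omega > 0}  log det Omega - tr(S Omega) - lambda * sum_{i != j} |Omega_ij|

with the diagonal unpenalized (optionally penalized).  Each sweep solves one
lasso subproblem per column of the working covariance estimate W, following
the classical row/column blockwise algorithm.  The hot path is compiled with
numba so that the bootstrap machinery can afford tens of thousands of full
penalty-path fits.

The convergence criterion is the maximum elementwise change of W between
sweeps (default 1e-6).  At ``lam = 0`` the solver converges to the plain
maximum-likelihood inverse of S.
"""

from __future__ import annotations

import numpy as np
from numba import njit


class GlassoConvergenceError(RuntimeError):
    """Raised when the blockwise solver does not converge.

    Carries the last between-sweep gap (max elementwise change of the working
    covariance) in :attr:`gap`.
    """

    def __init__(self, gap: float, max_sweeps: int):
        self.gap = gap
        self.max_sweeps = max_sweeps
        super().__init__(
            f"graphical lasso did not converge after {max_sweeps} sweeps "
            f"(last max elementwise change {gap:.3e})"
        )


@njit(cache=True)
def _lasso_cd(W11, s12, lam, beta, max_iter, tol):  # pragma: no cover - jit
    q = s12.shape[0]
    for _ in range(max_iter):
        dmax = 0.0
        for k in range(q):
            r = s12[k]
            for m in range(q):
                if m != k:
                    r -= W11[k, m] * beta[m]
            if r > lam:
                b = (r - lam) / W11[k, k]
            elif r < -lam:
                b = (r + lam) / W11[k, k]
            else:
                b = 0.0
            d = abs(b - beta[k])
            if d > dmax:
                dmax = d
            beta[k] = b
        if dmax < tol:
            break
    return beta


@njit(cache=True)
def _glasso_inplace(S, lam, W, B, max_sweeps, tol):  # pragma: no cover - jit
    """One glasso solve; W and B are warm-start state updated in place.

    Returns (precision, gap, n_sweeps).  B[:, j] holds the lasso coefficients
    of column j against the remaining variables.
    """
    p = S.shape[0]
    W11 = np.empty((p - 1, p - 1))
    s12 = np.empty(p - 1)
    gap = 0.0
    sweeps = 0
    for sweep in range(max_sweeps):
        gap = 0.0
        for j in range(p):
            # gather the (p-1) block excluding row/column j
            a = 0
            for r in range(p):
                if r == j:
                    continue
                s12[a] = S[r, j]
                b = 0
                for c in range(p):
                    if c == j:
                        continue
                    W11[a, b] = W[r, c]
                    b += 1
                a += 1
            beta = B[:, j]
            _lasso_cd(W11, s12, lam, beta, 200, tol * 0.1)
            # w12 = W11 @ beta, written back into row/column j
            a = 0
            for r in range(p):
                if r == j:
                    continue
                w_new = 0.0
                for m in range(p - 1):
                    w_new += W11[a, m] * beta[m]
                d = abs(w_new - W[r, j])
                if d > gap:
                    gap = d
                W[r, j] = w_new
                W[j, r] = w_new
                a += 1
        sweeps = sweep + 1
        if gap < tol:
            break
    # recover the precision matrix from the final W and regression coefficients
    Omega = np.zeros((p, p))
    for j in range(p):
        dot = 0.0
        a = 0
        for r in range(p):
            if r == j:
                continue
            dot += W[r, j] * B[a, j]
            a += 1
        ojj = 1.0 / (W[j, j] - dot)
        Omega[j, j] = ojj
        a = 0
        for r in range(p):
            if r == j:
                continue
            Omega[r, j] = -B[a, j] * ojj
            a += 1
    # symmetrize (columnwise recovery is asymmetric at finite tolerance)
    for r in range(p):
        for c in range(r + 1, p):
            v = 0.5 * (Omega[r, c] + Omega[c, r])
            Omega[r, c] = v
            Omega[c, r] = v
    return Omega, gap, sweeps


@njit(cache=True)
def _glasso_path_jit(S, lambdas, penalize_diagonal, max_sweeps, tol):  # pragma: no cover
    p = S.shape[0]
    n_lam = lambdas.shape[0]
    precisions = np.empty((n_lam, p, p))
    gaps = np.empty(n_lam)
    W = S.copy()
    B = np.zeros((p - 1, p))
    for i in range(n_lam):
        lam = lambdas[i]
        if penalize_diagonal:
            for d in range(p):
                W[d, d] = S[d, d] + lam
        Omega, gap, _ = _glasso_inplace(S, lam, W, B, max_sweeps, tol)
        precisions[i] = Omega
        gaps[i] = gap
    return precisions, gaps


def glasso_fit(
    S: np.ndarray,
    lam: float,
    *,
    penalize_diagonal: bool = False,
    max_sweeps: int = 1000,
    tol: float = 1e-6,
) -> np.ndarray:
    """Fit one graphical-lasso precision matrix at penalty ``lam``.

    Parameters
    ----------
    S : (p, p) ndarray
        Sample covariance/correlation matrix (symmetric).
    lam : float
        Nonnegative L1 penalty on the off-diagonal precision entries.

    Returns
    -------
    (p, p) ndarray
        The estimated positive-definite precision matrix, with exact zeros in
        entries shrunk away by the penalty.
    """
    S = np.ascontiguousarray(S, dtype=np.float64)
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    p = S.shape[0]
    W = S.copy()
    if penalize_diagonal:
        W[np.diag_indices(p)] += lam
    B = np.zeros((p - 1, p))
    Omega, gap, sweeps = _glasso_inplace(S, lam, W, B, max_sweeps, tol)
    if sweeps >= max_sweeps and gap >= tol:
        raise GlassoConvergenceError(gap, max_sweeps)
    return Omega


def glasso_path(
    S: np.ndarray,
    lambdas: np.ndarray,
    *,
    penalize_diagonal: bool = False,
    max_sweeps: int = 1000,
    tol: float = 1e-6,
) -> np.ndarray:
    """Warm-started glasso fits along a decreasing penalty sequence.

    Returns an ``(len(lambdas), p, p)`` stack of precision matrices.
    """
    S = np.ascontiguousarray(S, dtype=np.float64)
    lambdas = np.ascontiguousarray(lambdas, dtype=np.float64)
    precisions, gaps = _glasso_path_jit(S, lambdas, penalize_diagonal, max_sweeps, tol)
    worst = float(np.max(gaps))
    if worst >= tol:
        raise GlassoConvergenceError(worst, max_sweeps)
    return precisions


def partial_correlations(precision: np.ndarray) -> np.ndarray:
    """Edge weights of a Gaussian graphical model from its precision matrix.

    ``w_ij = -Omega_ij / sqrt(Omega_ii * Omega_jj)``, with a zero diagonal.
    """
    precision = np.asarray(precision, dtype=float)
    d = np.diag(precision)
    if np.any(d <= 0):
        raise ValueError("precision matrix has non-positive diagonal entries")
    scale = np.sqrt(d)
    weights = -precision / np.outer(scale, scale)
    weights = 0.5 * (weights + weights.T)
    np.fill_diagonal(weights, 0.0)
    return weights
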