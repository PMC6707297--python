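"""Low-level coordinate-descent solvers for the weighted elastic net.

Objective, on standardized predictors and centered response:

    (1/2n) ||y - X b||^2 + lam * sum_j v_j * (alpha |b_j| + (1-alpha)/2 b_j^2)

with per-predictor penalty factors v_j in [0, 1].  The path solver works on
the Gram matrix (covariance updates) and is numba-jitted because nested
cross-validation visits it tens of thousands of times.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency
    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=True)
def cd_path(gram, xty, v, alpha, lambdas, tol, max_iter):
    """Coordinate-descent solution path over a decreasing lambda grid.

    gram = X^T X / n, xty = X^T y / n on the standardized scale.  Returns an
    (n_lambda, p) array of coefficients; warm starts carry along the path.
    """
    p = gram.shape[0]
    nl = lambdas.shape[0]
    betas = np.zeros((nl, p))
    beta = np.zeros(p)
    for li in range(nl):
        lam = lambdas[li]
        for _ in range(max_iter):
            maxd = 0.0
            for j in range(p):
                dj = gram[j, j]
                if dj <= 0.0:
                    continue
                old = beta[j]
                rho = xty[j] + dj * old
                for k in range(p):
                    rho -= gram[j, k] * beta[k]
                thr = lam * alpha * v[j]
                if rho > thr:
                    new = (rho - thr) / (dj + lam * (1.0 - alpha) * v[j])
                elif rho < -thr:
                    new = (rho + thr) / (dj + lam * (1.0 - alpha) * v[j])
                else:
                    new = 0.0
                if new != old:
                    beta[j] = new
                    d = abs(new - old)
                    if d > maxd:
                        maxd = d
            if maxd < tol:
                break
        betas[li] = beta
    return betas


def standardize(X: np.ndarray):
    """Column-standardize (population SD); zero-variance columns get sd 1."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd <= 1e-12, 1.0, sd)
    return (X - mean) / sd, mean, sd


def lambda_path(xty: np.ndarray, v: np.ndarray, alpha: float,
                n_lambda: int = 100, min_ratio: float = 1e-3) -> np.ndarray:
    """Log-spaced grid from lambda_max (all-zero solution) downward.

    lambda_max accounts for the smallest penalty factor: a predictor with
    v_j < 1 enters earlier, so lambda_max = max_j |xty_j| / (alpha v_j).
    """
    a = max(alpha, 1e-3)
    vv = np.clip(v, 1e-8, None)
    lam_max = float(np.max(np.abs(xty) / (a * vv)))
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def enet_objective(Xs: np.ndarray, yc: np.ndarray, beta: np.ndarray,
                   v: np.ndarray, alpha: float, lam: float) -> float:
    n = Xs.shape[0]
    resid = yc - Xs @ beta
    pen = np.sum(v * (alpha * np.abs(beta) + 0.5 * (1 - alpha) * beta**2))
    return float(resid @ resid / (2 * n) + lam * pen)


def cd_single(Xs: np.ndarray, yc: np.ndarray, v: np.ndarray, alpha: float,
              lam: float, tol: float = 1e-8, max_iter: int = 1000,
              beta0=None):
    """Single-lambda cyclic coordinate descent recording the objective per sweep.

    Returns (beta, objective_trace, converged).  Pure python/numpy; used for
    one-off fits where the per-sweep objective trace matters.
    """
    n, p = Xs.shape
    gram = Xs.T @ Xs / n
    xty = Xs.T @ yc / n
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    trace = [enet_objective(Xs, yc, beta, v, alpha, lam)]
    converged = False
    diag = np.diag(gram)
    for _ in range(max_iter):
        maxd = 0.0
        for j in range(p):
            if diag[j] <= 0:
                continue
            rho = xty[j] - gram[j] @ beta + diag[j] * beta[j]
            thr = lam * alpha * v[j]
            new = 0.0
            if rho > thr:
                new = (rho - thr) / (diag[j] + lam * (1 - alpha) * v[j])
            elif rho < -thr:
                new = (rho + thr) / (diag[j] + lam * (1 - alpha) * v[j])
            maxd = max(maxd, abs(new - beta[j]))
            beta[j] = new
        trace.append(enet_objective(Xs, yc, beta, v, alpha, lam))
        if maxd < tol:
            converged = True
            break
    return beta, trace, converged
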