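"""L1-penalized least squares by cyclic coordinate descent.

Solves, for a single response vector,

    minimize_{b0, beta}  (1/2n) * sum_i (y_i - b0 - x_i' beta)^2 + lam * ||beta||_1

with an unpenalized intercept.  The intercept is handled by centering: the
problem is solved on column-centered X and centered y, and the intercept is
recovered as ``mean(y) - mean(X) @ beta``.

The design matrices in network inference are short (a handful to a few dozen
candidate regulators per gene), so the solver works on the p x p Gram matrix
and each full sweep costs O(p^2) independent of the number of samples.  The
inner sweep is JIT-compiled when numba is available (it is pure-Python
otherwise), which matters for the cross-validated penalty-grid search.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "soft_threshold",
    "lambda_max",
    "lasso_fit",
    "lasso_path",
    "lasso_objective",
    "kkt_residuals",
]


def soft_threshold(z: np.ndarray | float, t: float):
    """Elementwise soft-thresholding operator S(z, t) = sign(z) * max(|z| - t, 0)."""
    return np.sign(z) * np.maximum(np.abs(z) - t, 0.0)


def _cd_gram(G, c, diag, usable, lam, beta, max_iter, tol):
    """Cyclic coordinate descent on the Gram system; beta updated in place."""
    p = beta.shape[0]
    Gb = G @ beta
    for _ in range(max_iter):
        max_delta = 0.0
        for j in range(p):
            if not usable[j]:
                continue
            b_old = beta[j]
            z = c[j] - Gb[j] + diag[j] * b_old
            az = abs(z) - lam
            b_new = (az if z > 0 else -az) / diag[j] if az > 0 else 0.0
            if b_new != b_old:
                delta = b_new - b_old
                for i in range(p):
                    Gb[i] += G[i, j] * delta
                beta[j] = b_new
                if abs(delta) > max_delta:
                    max_delta = abs(delta)
        if max_delta < tol:
            break
    return beta


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _cd_gram = njit(cache=True)(_cd_gram)
except ImportError:  # pragma: no cover
    pass


def _center(X: np.ndarray, y: np.ndarray):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    return X - x_mean, y - y_mean, x_mean, y_mean


def _gram(Xc: np.ndarray, yc: np.ndarray):
    n = Xc.shape[0]
    G = Xc.T @ Xc / n
    c = Xc.T @ yc / n
    diag = np.ascontiguousarray(np.diag(G))
    usable = diag > 0  # constant columns carry no information
    return G, c, diag, usable


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which every coefficient is zero (KKT bound).

    Computed on centered data: lam_max = max_j |x_j' y| / n.
    """
    Xc, yc, _, _ = _center(X, y)
    n = Xc.shape[0]
    if Xc.size == 0 or Xc.shape[1] == 0:
        return 0.0
    return float(np.max(np.abs(Xc.T @ yc)) / n)


def lasso_fit(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    *,
    beta_init: np.ndarray | None = None,
    max_iter: int = 100_000,
    tol: float = 1e-12,
):
    """Fit the lasso at a single penalty value.

    Parameters
    ----------
    X : (n, p) design matrix (not necessarily standardized).
    y : (n,) response.
    lam : penalty on the (1/2n) least-squares scale; must be >= 0.
    beta_init : optional warm start.
    tol : convergence threshold on the largest single-coordinate update.

    Returns
    -------
    (intercept, beta) with beta of shape (p,).
    """
    if lam < 0:
        raise ValueError("penalty must be nonnegative")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    p = X.shape[1] if X.ndim == 2 else 0
    if p == 0:
        return float(np.mean(y)), np.zeros(0)
    Xc, yc, x_mean, y_mean = _center(X, y)
    G, c, diag, usable = _gram(Xc, yc)
    beta = np.zeros(p) if beta_init is None else np.array(beta_init, dtype=float)
    beta[~usable] = 0.0
    beta = _cd_gram(G, c, diag, usable, float(lam), beta, max_iter, tol)
    intercept = y_mean - float(x_mean @ beta)
    return intercept, beta


def lasso_path(
    X: np.ndarray,
    y: np.ndarray,
    lams: np.ndarray,
    *,
    max_iter: int = 100_000,
    tol: float = 1e-10,
):
    """Fit along a (descending) penalty sequence with warm starts.

    Returns ``(intercepts, betas)`` with betas of shape (len(lams), p).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    p = X.shape[1]
    betas = np.zeros((len(lams), p))
    if p == 0:
        return np.full(len(lams), float(np.mean(y))), betas
    Xc, yc, x_mean, y_mean = _center(X, y)
    G, c, diag, usable = _gram(Xc, yc)
    beta = np.zeros(p)
    for i, lam in enumerate(lams):
        beta = _cd_gram(G, c, diag, usable, float(lam), beta, max_iter, tol)
        betas[i] = beta
    intercepts = y_mean - betas @ x_mean
    return intercepts, betas


def lasso_objective(X, y, intercept: float, beta: np.ndarray, lam: float) -> float:
    """(1/2n) residual sum of squares plus lam * L1 norm of beta."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    r = y - intercept - X @ beta
    return float(r @ r / (2 * n) + lam * np.abs(beta).sum())


def kkt_residuals(X, y, intercept: float, beta: np.ndarray, lam: float) -> np.ndarray:
    """Per-coordinate violation of the lasso stationarity conditions.

    For beta_j = 0 the subgradient condition requires |x_j' r / n| <= lam;
    for beta_j != 0 it requires x_j' r / n = lam * sign(beta_j).  Returns the
    nonnegative violation for each coordinate (all ~0 at an exact optimum).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    g = X.T @ (y - intercept - X @ beta) / n
    viol = np.where(
        beta == 0.0,
        np.maximum(np.abs(g) - lam, 0.0),
        np.abs(g - lam * np.sign(beta)),
    )
    return viol
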