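"""Small Newton–Raphson logistic solver used inside the LOO classifier.

Leave-one-out evaluation and its permutation/multi-seed checks refit a tiny
logistic model thousands of times; this solver keeps per-fit overhead low and
handles complete separation uniformly: a fit that diverges (coefficients
running away, singular Hessian, or non-convergence) is retried with a small
L2 ridge penalty (1e-6 by default) and marked ``penalized``.  User-facing
inference elsewhere in the package goes through statsmodels; agreement of
this solver with statsmodels is asserted in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

#: |coefficient| beyond which a fit is treated as separated/diverging.
_DIVERGENCE_BOUND = 30.0


@dataclass
class LogisticSolve:
    beta: np.ndarray          # includes intercept (column 0)
    cov: np.ndarray | None    # inverse (penalized) Fisher information
    converged: bool
    penalized: bool
    n_iter: int


def _newton(X: np.ndarray, y: np.ndarray, ridge: float,
            max_iter: int = 60, tol: float = 1e-10) -> LogisticSolve:
    n, p = X.shape
    beta = np.zeros(p)
    pen = np.full(p, ridge)
    pen[0] = 0.0  # never penalize the intercept
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        wdiag = mu * (1.0 - mu)
        grad = X.T @ (y - mu) - pen * beta
        H = (X * wdiag[:, None]).T @ X + np.diag(pen)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return LogisticSolve(beta, None, False, ridge > 0, it)
        beta = beta + step
        if np.max(np.abs(beta)) > _DIVERGENCE_BOUND and ridge == 0.0:
            return LogisticSolve(beta, None, False, False, it)
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = X @ beta
    mu = expit(eta)
    wdiag = np.clip(mu * (1.0 - mu), 1e-12, None)
    H = (X * wdiag[:, None]).T @ X + np.diag(pen)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = None
    return LogisticSolve(beta, cov, converged, ridge > 0, it)


def fit_logistic(X: np.ndarray, y: np.ndarray,
                 ridge_eps: float = 1e-6) -> LogisticSolve:
    """ML logistic fit with automatic tiny-ridge fallback on separation.

    *X* must already contain an intercept column first; *y* is 0/1.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.shape[0] != X.shape[0]:
        raise ValueError("X must be (n, p) and y length n")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    fit = _newton(X, y, ridge=0.0)
    if fit.converged and fit.cov is not None:
        return fit
    return _newton(X, y, ridge=ridge_eps, max_iter=200)


def predict_proba(fit: LogisticSolve, X: np.ndarray) -> np.ndarray:
    return expit(np.asarray(X, dtype=float) @ fit.beta)
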