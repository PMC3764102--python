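"""Single-marker linear mixed model with a kinship random effect.

Fits, by restricted maximum likelihood, the model

    y = X b + u + e,   cov(u) = sg2 * K,   cov(e) = se2 * I,

profiling the variance ratio delta = se2 / sg2 on the spectrum of the
projected kinship matrix, so each fit needs only one symmetric
eigendecomposition plus a one-dimensional optimisation.  The Wald test on a
coefficient uses n - q degrees of freedom; with K = I it reduces exactly to
the ordinary-least-squares F test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = ["REMLResult", "fit_reml"]

_LOG10_BOUNDS = (-5.0, 5.0)
_GRID_SIZE = 100


@dataclass
class REMLResult:
    """REML fit of a kinship mixed model.

    Attributes
    ----------
    beta, se : coefficient estimates and standard errors (length q).
    p_wald : two-sided Wald p-values on n - q degrees of freedom.
    sigma_g2, sigma_e2 : genetic and residual variance components.
    delta : fitted ratio sigma_e2 / sigma_g2.
    loglik : restricted log-likelihood at the optimum (up to a constant).
    df : residual degrees of freedom n - q.
    """

    beta: np.ndarray
    se: np.ndarray
    p_wald: np.ndarray
    sigma_g2: float
    sigma_e2: float
    delta: float
    loglik: float
    df: int


def _reml_crit(delta: float, lam: np.ndarray, eta2: np.ndarray, nq: int) -> float:
    denom = lam + delta
    rss = float(np.sum(eta2 / denom))
    return -0.5 * (nq * np.log(rss) + float(np.sum(np.log(denom))))


def _reml_grad(delta: float, lam: np.ndarray, eta2: np.ndarray, nq: int) -> float:
    denom = lam + delta
    rss = float(np.sum(eta2 / denom))
    return 0.5 * (nq * float(np.sum(eta2 / denom**2)) / rss - float(np.sum(1.0 / denom)))


def fit_reml(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray,
    *,
    delta: float | None = None,
) -> REMLResult:
    """Fit the mixed model by REML and Wald-test each coefficient.

    Parameters
    ----------
    y : response vector, length n.
    X : fixed-effect design, n x q (include the intercept column).
    K : n x n positive semidefinite relatedness matrix.
    delta : if given, the variance ratio is held fixed (approximate mode in
        which a previously estimated ratio is reused across markers) instead
        of being re-estimated.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    K = np.asarray(K, dtype=float)
    n, q = X.shape
    if y.shape != (n,):
        raise ValueError("y and X have incompatible shapes")
    if K.shape != (n, n):
        raise ValueError("K must be n x n")
    nq = n - q
    if nq < 1:
        raise ValueError("model is saturated: n <= q")

    XtX = X.T @ X
    if np.linalg.matrix_rank(XtX) < q:
        raise ValueError("design matrix is rank deficient")
    P = X @ np.linalg.solve(XtX, X.T)
    S = np.eye(n) - P
    M = S @ K @ S
    M = 0.5 * (M + M.T)
    w, V = np.linalg.eigh(M)
    if w[0] < -1e-6 * max(1.0, abs(w[-1])):
        raise ValueError("kinship matrix is not positive semidefinite")
    order = np.argsort(w)[::-1][:nq]
    lam = np.clip(w[order], 0.0, None)
    eta = V[:, order].T @ y
    eta2 = eta**2
    if np.sum(eta2) <= 0:
        raise ValueError("response is constant after projection")

    if delta is None:
        grid = 10.0 ** np.linspace(*_LOG10_BOUNDS, _GRID_SIZE)
        denom = lam[None, :] + grid[:, None]
        rss = np.sum(eta2[None, :] / denom, axis=1)
        crit = -0.5 * (nq * np.log(rss) + np.sum(np.log(denom), axis=1))
        i = int(np.argmax(crit))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, _GRID_SIZE - 1)]
        glo = _reml_grad(lo, lam, eta2, nq)
        ghi = _reml_grad(hi, lam, eta2, nq)
        if glo > 0 and ghi < 0:
            delta_hat = optimize.brentq(
                _reml_grad, lo, hi, args=(lam, eta2, nq), xtol=1e-12, rtol=1e-14
            )
        else:  # optimum on the grid boundary
            delta_hat = grid[i]
    else:
        if delta <= 0:
            raise ValueError("delta must be positive")
        delta_hat = float(delta)

    dvec = lam + delta_hat
    rss = float(np.sum(eta2 / dvec))
    sigma_g2 = rss / nq
    sigma_e2 = delta_hat * sigma_g2
    loglik = _reml_crit(delta_hat, lam, eta2, nq)

    H = K + delta_hat * np.eye(n)
    Hinv_X = np.linalg.solve(H, X)
    Hinv_y = np.linalg.solve(H, y)
    A = X.T @ Hinv_X
    beta = np.linalg.solve(A, X.T @ Hinv_y)
    cov = np.linalg.inv(A) * sigma_g2
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * stats.t.sf(np.abs(tstat), nq)
    return REMLResult(
        beta=beta,
        se=se,
        p_wald=p,
        sigma_g2=sigma_g2,
        sigma_e2=sigma_e2,
        delta=delta_hat,
        loglik=loglik,
        df=nq,
    )
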