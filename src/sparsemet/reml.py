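"""Restricted maximum likelihood for linear mixed models in kernel form.

The model is y = X b + sum_i u_i + e with var(u_i) = sigma_i^2 K_i for known
positive semidefinite N x N kernels K_i (e.g. Z A Z' for a design matrix Z and
covariance structure A) and var(e) = sigma_e^2 I. Variance components are
estimated by average-information (AI) REML with step-halving and a fixed-point
fallback; the REML log-likelihood is guaranteed non-decreasing across accepted
iterations.

This is the single estimation engine behind stage-one trial analysis and the
multi-environment genomic prediction model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

__all__ = ["RemlResult", "reml", "reml_loglik", "gls_fixed_effects"]


@dataclass
class RemlResult:
    """Variance-component estimates and fit diagnostics.

    ``varcomps`` holds one entry per kernel plus the residual variance last;
    ``names`` matches. ``loglik_trace`` records the (restricted) log-likelihood
    at every accepted iterate.
    """

    varcomps: np.ndarray
    names: list[str]
    loglik: float
    converged: bool
    n_iter: int
    loglik_trace: list[float] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.names, self.varcomps)}


def _validate(y: np.ndarray, X: np.ndarray, kernels: list[np.ndarray]):
    y = np.asarray(y, float).ravel()
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != y.size:
        X = X.T
    n = y.size
    if X.shape[0] != n:
        raise ValueError("X row count does not match y")
    ks = []
    for K in kernels:
        K = np.asarray(K, float)
        if K.shape != (n, n):
            raise ValueError("kernel shape does not match data size")
        ks.append(K)
    return y, X, ks


def _pieces(y, X, kernels, theta):
    """Log-likelihood, score and AI matrix at variance components theta."""
    n = y.size
    V = theta[-1] * np.eye(n)
    for t, K in zip(theta[:-1], kernels):
        V += t * K
    L, low = linalg.cho_factor(V, lower=True, check_finite=False)
    logdetV = 2.0 * np.sum(np.log(np.diag(L)))
    Vinv = linalg.cho_solve((L, low), np.eye(n), check_finite=False)
    VinvX = Vinv @ X
    XtVinvX = X.T @ VinvX
    sign, logdetXVX = np.linalg.slogdet(XtVinvX)
    if sign <= 0:
        raise np.linalg.LinAlgError("X'V^-1X not positive definite")
    P = Vinv - VinvX @ np.linalg.solve(XtVinvX, VinvX.T)
    Py = P @ y
    ll = -0.5 * (logdetV + logdetXVX + float(y @ Py))
    # score_i = -0.5 (tr(P K_i) - y'P K_i P y); residual kernel is I
    KPy = [K @ Py for K in kernels] + [Py]
    trPK = [float(np.sum(P * K)) for K in kernels] + [float(np.trace(P))]
    quad = [float(Py @ t) for t in KPy]
    score = -0.5 * (np.array(trPK) - np.array(quad))
    T = np.column_stack(KPy)
    AI = 0.5 * (T.T @ P @ T)
    return ll, score, AI, np.array(quad), np.array(trPK)


def reml(
    y: np.ndarray,
    X: np.ndarray,
    kernels: list[np.ndarray],
    names: list[str] | None = None,
    init: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
    floor: float = 1e-10,
) -> RemlResult:
    """Estimate variance components by AI-REML.

    Parameters
    ----------
    y, X : data vector and fixed-effect design (full column rank).
    kernels : list of N x N PSD matrices, one per random term; the residual
        identity kernel is implicit and its variance is reported last.
    init : starting values (len(kernels) + 1); default splits the OLS residual
        variance equally.
    tol : convergence threshold on the change in restricted log-likelihood.
    floor : lower bound applied to every component (relative to total
        variance scale) to keep the covariance invertible.

    Notes
    -----
    AI steps are halved until the likelihood does not decrease and all
    components stay above the floor; if no AI step is acceptable, a
    positivity-preserving fixed-point update
    sigma_i^2 <- sigma_i^2 * (y'P K_i P y) / tr(P K_i) is taken instead.
    """
    y, X, kernels = _validate(y, X, kernels)
    k = len(kernels)
    if names is None:
        names = [f"k{i}" for i in range(k)] + ["residual"]
    if len(names) != k + 1:
        raise ValueError("need one name per kernel plus residual")
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_ols
    scale = max(float(resid @ resid) / max(y.size - X.shape[1], 1), 1e-12)
    lo = max(floor, floor * scale)
    if init is None:
        theta = np.full(k + 1, scale / (k + 1))
    else:
        theta = np.asarray(init, float).copy()
    theta = np.maximum(theta, lo)

    ll, score, AI, quad, trPK = _pieces(y, X, kernels, theta)
    trace = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # active set: components stuck at the floor whose score pushes them
        # further down are held fixed, otherwise they force endless tiny steps
        free = ~((theta <= lo * 1.001) & (score < 0))
        if not free.any():
            converged = True
            break
        delta = np.zeros_like(theta)
        AIf = AI[np.ix_(free, free)]
        try:
            delta[free] = np.linalg.solve(AIf, score[free])
        except np.linalg.LinAlgError:
            delta[free] = np.linalg.pinv(AIf) @ score[free]
        accepted = False
        step = 1.0
        for _ in range(25):
            cand = np.maximum(theta + step * delta, lo)
            try:
                cll, cscore, cAI, cquad, ctr = _pieces(y, X, kernels, cand)
            except np.linalg.LinAlgError:
                step *= 0.5
                continue
            if cll >= ll - 1e-12:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            # fixed-point fallback: positive by construction
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(trPK > 0, quad / trPK, 1.0)
            cand = np.maximum(theta * ratio, lo)
            try:
                cll, cscore, cAI, cquad, ctr = _pieces(y, X, kernels, cand)
            except np.linalg.LinAlgError:
                break
            if cll < ll - 1e-8:
                break  # cannot improve; stop at current iterate
        change = cll - ll
        theta, ll, score, AI, quad, trPK = cand, cll, cscore, cAI, cquad, ctr
        trace.append(ll)
        if abs(change) < tol:
            converged = True
            break
    return RemlResult(
        varcomps=theta,
        names=list(names),
        loglik=float(ll),
        converged=converged,
        n_iter=it,
        loglik_trace=trace,
    )


def reml_loglik(y, X, kernels, theta) -> float:
    """Restricted log-likelihood at given variance components."""
    y, X, kernels = _validate(y, X, kernels)
    ll, *_ = _pieces(y, X, kernels, np.asarray(theta, float))
    return ll


def gls_fixed_effects(y, X, kernels, theta):
    """GLS estimate of the fixed effects and V^{-1} residual pieces.

    Returns (beta_hat, Vinv_resid) with Vinv_resid = V^{-1}(y - X beta_hat),
    the workhorse vector for computing BLUPs of any random term as
    sigma_i^2 A_i Z_i' V^{-1}(y - X beta_hat).
    """
    y, X, kernels = _validate(y, X, kernels)
    theta = np.asarray(theta, float)
    n = y.size
    V = theta[-1] * np.eye(n)
    for t, K in zip(theta[:-1], kernels):
        V += t * K
    cf = linalg.cho_factor(V, lower=True, check_finite=False)
    VinvX = linalg.cho_solve(cf, X, check_finite=False)
    beta = np.linalg.solve(X.T @ VinvX, VinvX.T @ y)
    r = linalg.cho_solve(cf, y - X @ beta, check_finite=False)
    return beta, r
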