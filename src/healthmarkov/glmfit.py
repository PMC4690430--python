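"""Posterior-weighted regression fits used inside the EM M-step.

The multinomial (and binary) logit solver maximises a weighted multinomial
log-likelihood where each observation carries a fractional weight per
category -- exactly the shape of E-step posteriors.  It is a damped Newton
method with step-halving, iterated to full convergence so every M-step is a
genuine maximiser (which is what guarantees the EM ascent property).

The Gamma mean model goes through statsmodels' GLM with variance weights;
the shared shape parameter is a one-dimensional profile-likelihood solve.
"""

from __future__ import annotations

import numpy as np
import statsmodels.api as sm
from scipy.optimize import brentq
from scipy.special import digamma, gammaln

__all__ = ["weighted_softmax_fit", "weighted_gamma_fit", "weighted_gamma_loglik"]


def _softmax_loglik(eta: np.ndarray, W: np.ndarray) -> float:
    # eta (n, K) linear predictors (reference column included as zeros)
    lse = np.log(np.exp(eta - eta.max(axis=1, keepdims=True)).sum(axis=1)) + eta.max(axis=1)
    return float((W * eta).sum() - (W.sum(axis=1) * lse).sum())


def weighted_softmax_fit(
    X: np.ndarray,
    W: np.ndarray,
    reference: int = 0,
    start: np.ndarray | None = None,
    tol: float = 1e-9,
    max_iter: int = 200,
) -> np.ndarray:
    """Maximum-likelihood multinomial logit with per-category weights.

    Parameters
    ----------
    X : (n, p) design matrix.
    W : (n, K) non-negative weights (fractional category counts).
    reference : category whose coefficient row is pinned at zero.
    start : optional (K, p) warm start (reference row ignored).

    Returns
    -------
    coef : (K, p) with ``coef[reference] == 0``.
    """
    X = np.asarray(X, dtype=float)
    W = np.asarray(W, dtype=float)
    n, p = X.shape
    K = W.shape[1]
    free = [k for k in range(K) if k != reference]
    nf = len(free)
    beta = np.zeros((K, p))
    if start is not None:
        beta[:] = start
        beta[reference] = 0.0

    wtot = W.sum(axis=1)
    ll = _softmax_loglik(X @ beta.T, W)
    for _ in range(max_iter):
        eta = X @ beta.T
        Pm = np.exp(eta - eta.max(axis=1, keepdims=True))
        Pm /= Pm.sum(axis=1, keepdims=True)
        # gradient for free categories
        resid = W - wtot[:, None] * Pm          # (n, K)
        grad = (resid[:, free].T @ X).ravel()   # (nf * p,)
        if np.max(np.abs(grad)) < tol * max(1.0, np.abs(ll)):
            break
        # Fisher information blocks
        H = np.empty((nf * p, nf * p))
        for a, ka in enumerate(free):
            for b, kb in enumerate(free):
                wab = wtot * Pm[:, ka] * ((ka == kb) - Pm[:, kb])
                H[a * p : (a + 1) * p, b * p : (b + 1) * p] = (X * wab[:, None]).T @ X
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(nf * p), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step-halving line search on the weighted log-likelihood
        scale = 1.0
        for _ in range(40):
            cand = beta.copy()
            cand[free] += scale * step.reshape(nf, p)
            ll_new = _softmax_loglik(X @ cand.T, W)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta = cand
        if ll_new - ll < tol * max(1.0, abs(ll)):
            ll = ll_new
            break
        ll = ll_new
    beta[reference] = 0.0
    return beta


def weighted_gamma_loglik(y: np.ndarray, mu: np.ndarray, shape: float, w: np.ndarray) -> float:
    """Weighted Gamma log-likelihood (mean/shape parameterisation)."""
    return float(
        np.sum(
            w
            * (
                shape * (np.log(shape) - np.log(mu))
                - gammaln(shape)
                + (shape - 1.0) * np.log(y)
                - shape * y / mu
            )
        )
    )


def _gamma_quasi_ll(eta, y, w):
    return float(np.sum(w * (-y * np.exp(-eta) - eta)))


def _gamma_irls_robust(X, y, w, start=None, tol=1e-10, max_iter=200):
    """Damped Fisher scoring for the Gamma log-link mean, with clipped
    predictors; survives near-separated, tiny-effective-sample subproblems."""
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = np.log(np.average(y, weights=np.maximum(w, 1e-300)))
    if start is not None and np.all(np.isfinite(start)):
        beta = np.asarray(start, dtype=float).copy()
    eta = np.clip(X @ beta, -30.0, 30.0)
    ll = _gamma_quasi_ll(eta, y, w)
    H = X.T @ (w[:, None] * X) + 1e-9 * np.eye(p)
    for _ in range(max_iter):
        mu = np.exp(eta)
        grad = X.T @ (w * (y - mu) / mu)
        if np.max(np.abs(grad)) < tol * max(1.0, abs(ll)):
            break
        step = np.linalg.solve(H, grad)
        scale = 1.0
        for _ in range(50):
            eta_new = np.clip(X @ (beta + scale * step), -30.0, 30.0)
            ll_new = _gamma_quasi_ll(eta_new, y, w)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        if ll_new - ll < tol * max(1.0, abs(ll)):
            eta, ll = eta_new, ll_new
            break
        eta, ll = eta_new, ll_new
    return beta, np.exp(eta)


def weighted_gamma_fit(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    start: np.ndarray | None = None,
):
    """Weighted Gamma GLM with log link; returns (coef, fitted_means).

    The coefficient estimate maximises the weighted likelihood for any fixed
    shape, so the shape can be profiled out separately.  statsmodels' IRLS is
    used when it succeeds; a damped, clipped Fisher-scoring fallback handles
    the degenerate weighted subproblems it cannot.
    """
    try:
        model = sm.GLM(
            y, X, family=sm.families.Gamma(link=sm.families.links.Log()), var_weights=w
        )
        res = model.fit(start_params=start, maxiter=200, tol=1e-10)
        params = np.asarray(res.params)
        if np.all(np.isfinite(params)) and np.all(np.isfinite(res.mu)):
            return params, np.asarray(res.mu)
    except (ValueError, np.linalg.LinAlgError):
        pass
    return _gamma_irls_robust(X, y, w, start=start)


def solve_gamma_shape(y: np.ndarray, mu: np.ndarray, w: np.ndarray) -> float:
    """Profile-likelihood estimate of the shared Gamma shape parameter."""
    wsum = w.sum()
    if wsum <= 0:
        return 1.0
    s = float(np.sum(w * (np.log(mu) - np.log(y) + y / mu - 1.0)) / wsum)
    s = max(s, 1e-12)

    def f(a):
        return np.log(a) - digamma(a) - s

    lo, hi = 1e-4, 1e6
    if f(lo) < 0:
        return lo
    if f(hi) > 0:
        return hi
    return float(brentq(f, lo, hi, xtol=1e-10, rtol=1e-12))
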