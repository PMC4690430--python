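"""Forward-backward recursions and a brute-force likelihood oracle.

The observed-data likelihood of one individual is the sum over all latent
state paths of initial probability x annual transition probabilities x
emission terms, with missing emissions contributing factor 1.  The
forward-backward implementation uses per-step scaling and is numerically
stable for panels of at least 60 years; the brute-force enumeration is the
independent oracle for small T.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .emissions import emission_loglik_array
from .panel import PanelArrays
from .params import LatentModelParams

__all__ = ["forward_backward", "loglik_brute_force", "PosteriorSet"]


@dataclass
class PosteriorSet:
    """Smoothed posteriors from the E-step.

    ``gamma[i, t, m]`` is P(state_t = m | data_i); ``xi[i, t, l, m]`` is the
    joint P(state_t = l, state_{t+1} = m | data_i); ``loglik[i]`` is the
    individual's log-likelihood contribution.  Padded cells are zero.
    """

    gamma: np.ndarray
    xi: np.ndarray
    loglik: np.ndarray
    ids: np.ndarray | None = None

    @property
    def total_loglik(self) -> float:
        return float(self.loglik.sum())


def _batch_inputs(params: LatentModelParams, arrays: PanelArrays, services):
    logg = emission_loglik_array(params, arrays, services=services)
    N, T, M = logg.shape
    L = params.n_living
    pi = np.zeros((N, M))
    pi[:, :L] = params.initial_probs(arrays.x_init)
    # transition matrix for step t-1 -> t uses covariates at the origin year
    P = np.empty((N, max(T - 1, 0), M, M))
    if T > 1:
        P[:] = params.transition_matrix(arrays.x_trans[:, : T - 1])
    return logg, pi, P


def forward_backward_batch(
    params: LatentModelParams,
    arrays: PanelArrays,
    services: tuple[str, ...] = ("hospital",),
) -> PosteriorSet:
    """Scaled forward-backward over all individuals at once."""
    logg, pi, P = _batch_inputs(params, arrays, services)
    N, T, M = logg.shape
    valid = arrays.valid

    # per-cell max-shift keeps exp() in range; padded cells contribute 0
    shift = np.max(logg, axis=2)
    shift = np.where(np.isfinite(shift), shift, 0.0)
    g = np.exp(logg - shift[:, :, None])

    # pad steps beyond an individual's horizon with identity dynamics
    ident = np.eye(M)
    if T > 1:
        step_valid = valid[:, 1:]
        P = np.where(step_valid[:, :, None, None], P, ident)
        g = np.where(valid[:, :, None], g, 1.0)

    alpha = np.empty((N, T, M))
    c = np.empty((N, T))
    a = pi * g[:, 0]
    c[:, 0] = a.sum(axis=1)
    alpha[:, 0] = a / c[:, 0, None]
    for t in range(1, T):
        a = np.einsum("nl,nlm->nm", alpha[:, t - 1], P[:, t - 1]) * g[:, t]
        c[:, t] = a.sum(axis=1)
        alpha[:, t] = a / c[:, t, None]

    beta = np.empty((N, T, M))
    beta[:, T - 1] = 1.0
    xi = np.zeros((N, max(T - 1, 0), M, M))
    for t in range(T - 2, -1, -1):
        gb = g[:, t + 1] * beta[:, t + 1] / c[:, t + 1, None]
        beta[:, t] = np.einsum("nlm,nm->nl", P[:, t], gb)
        xi[:, t] = alpha[:, t, :, None] * P[:, t] * gb[:, None, :]

    gamma = alpha * beta
    gamma /= gamma.sum(axis=2, keepdims=True)
    gamma = np.where(valid[:, :, None], gamma, 0.0)
    if T > 1:
        xi = np.where(valid[:, 1:, None, None], xi, 0.0)

    loglik = np.where(valid, np.log(c) + shift, 0.0).sum(axis=1)
    return PosteriorSet(gamma=gamma, xi=xi, loglik=loglik, ids=arrays.ids)


def forward_backward(
    params: LatentModelParams,
    arrays: PanelArrays,
    individual: int = 0,
    services: tuple[str, ...] = ("hospital",),
):
    """Posteriors and log-likelihood for one individual's record sequence.

    Returns ``(gamma (T, M), xi (T-1, M, M), loglik)``.  Records must cover
    consecutive years (enforced when the panel was built).
    """
    post = forward_backward_batch(params, arrays, services=services)
    T = int(arrays.valid[individual].sum())
    return (
        post.gamma[individual, :T],
        post.xi[individual, : max(T - 1, 0)],
        float(post.loglik[individual]),
    )


def loglik_brute_force(
    params: LatentModelParams,
    arrays: PanelArrays,
    individual: int = 0,
    services: tuple[str, ...] = ("hospital",),
    max_t: int = 8,
) -> float:
    """Exact nested-sum likelihood by enumerating all M^T state paths.

    Oracle for :func:`forward_backward`; refuses T beyond ``max_t``.
    """
    logg, pi, P = _batch_inputs(params, arrays, services)
    T = int(arrays.valid[individual].sum())
    if T > max_t:
        raise ValueError(f"brute force refused for T={T} > {max_t}")
    M = params.n_states
    logpi = np.log(np.where(pi[individual] > 0, pi[individual], 1e-300))
    with np.errstate(divide="ignore"):
        logP = np.log(np.maximum(P[individual], 1e-300))
    lg = logg[individual]
    path_logs = []
    for path in np.ndindex(*([M] * T)):
        lp = logpi[path[0]] + lg[0, path[0]]
        for t in range(1, T):
            lp += logP[t - 1, path[t - 1], path[t]] + lg[t, path[t]]
        path_logs.append(lp)
    return float(logsumexp(path_logs))
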