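"""Measurement (emission) components of the latent Markov health model.

Each living state emits the seven categorical indicators through
intercept-only multinomial logits, and annual per-service costs through a
two-part model: a use logit times a Gamma density (log-link mean, shared
shape) for positive amounts, with a point mass ``1 - p_use`` at zero.

Missing indicators and unobserved services contribute a factor 1 to the
likelihood.  Death is observed exactly through vital status: the death state
emits likelihood 1 in the death year and 0 otherwise, while living states
have emission 0 in the death year.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, gammaln, log_expit

from .panel import PanelArrays
from .params import SERVICES, LatentModelParams

__all__ = ["indicator_prob", "cost_emission_density", "emission_likelihood"]

_LOG_ZERO = -1e30  # stand-in for log 0 that keeps array arithmetic finite


def indicator_prob(params: LatentModelParams, state: int, indicator: int, category: int) -> float:
    """P(y_j = category | living state) from the state-specific intercepts."""
    if state >= params.n_living or state < 0:
        raise ValueError("indicator emissions exist only for living states")
    return float(params.indicator_probs(indicator)[state, category])


def _gamma_logpdf(c, mean, shape):
    """Gamma log density parameterised by mean and shape."""
    c = np.asarray(c, dtype=float)
    return (
        shape * (np.log(shape) - np.log(mean))
        - gammaln(shape)
        + (shape - 1.0) * np.log(c)
        - shape * c / mean
    )


def _service_two_part(params: LatentModelParams, service: str):
    tp = params.costs.get(service)
    if tp is None:
        raise ValueError(f"no fitted cost model for service '{service}'")
    return tp


def _service_design(arrays: PanelArrays, tp) -> np.ndarray:
    """Cost design matrix matching the service's own calendar-year dummies."""
    cov = arrays.covariates
    if tp.year_levels is None or tuple(tp.year_levels) == tuple(cov.year_levels):
        return arrays.x_cost
    base = arrays.x_cost[..., : cov.n_trans]
    if len(tp.year_levels) > 1:
        dums = np.stack(
            [(arrays.year == y).astype(float) for y in tp.year_levels[1:]], axis=-1
        )
    else:
        dums = np.zeros(arrays.year.shape + (0,))
    return np.concatenate([base, dums], axis=-1)


def cost_emission_density(
    params: LatentModelParams,
    cost: float,
    state: int,
    x_cost: np.ndarray,
    service: str,
) -> float:
    """Two-part density of an annual cost amount given the living state.

    ``(1 - p_use)`` at cost 0; ``p_use * Gamma(cost; mean(x), shape)`` for
    cost > 0, with log-link mean.
    """
    if cost < 0:
        raise ValueError("costs must be non-negative")
    if state >= params.n_living or state < 0:
        raise ValueError("cost emissions exist only for living states")
    tp = _service_two_part(params, service)
    x = np.asarray(x_cost, dtype=float)
    p_use = expit(x @ tp.use_coef[state])
    if cost == 0:
        return float(1.0 - p_use)
    mean = np.exp(x @ tp.mean_coef[state])
    return float(p_use * np.exp(_gamma_logpdf(cost, mean, tp.shape)))


def emission_likelihood(
    params: LatentModelParams,
    state: int,
    *,
    indicators=None,
    costs: dict[str, float] | None = None,
    x_cost=None,
    died: bool = False,
) -> float:
    """Likelihood of one individual-year's observations given the state.

    ``indicators`` is a length-J sequence with None (or -1) for missing;
    ``costs`` maps service name to an observed amount (absent = unobserved).
    A record with nothing observed has likelihood 1 for every living state.
    """
    if died:
        return 1.0 if state == params.death_state else 0.0
    if state == params.death_state:
        return 0.0  # alive record: survival observed through vital status
    val = 1.0
    if indicators is not None:
        for j, k in enumerate(indicators):
            if k is None or (isinstance(k, (int, np.integer)) and k < 0):
                continue
            val *= indicator_prob(params, state, j, int(k))
    if costs:
        for service, c in costs.items():
            if c is None or (isinstance(c, float) and np.isnan(c)):
                continue
            val *= cost_emission_density(params, float(c), state, x_cost, service)
    return val


def emission_loglik_array(
    params: LatentModelParams,
    arrays: PanelArrays,
    services: tuple[str, ...] = ("hospital",),
) -> np.ndarray:
    """Log emission likelihood log g_m for every (individual, year, state).

    Returns (N, Tmax, M); padded cells are 0 (factor 1).  Living states get
    ``_LOG_ZERO`` in death years, the death state gets ``_LOG_ZERO`` in alive
    years.
    """
    N, T = arrays.valid.shape
    L, M = params.n_living, params.n_states
    logg = np.zeros((N, T, M))

    for j in range(arrays.scheme.n_indicators):
        logp = np.log(params.indicator_probs(j))  # (L, K)
        yj = arrays.y[:, :, j]
        obs = yj >= 0
        if not obs.any():
            continue
        cats = yj[obs]
        logg[:, :, :L][obs] += logp[:, cats].T

    for service in services:
        tp = params.costs.get(service)
        if tp is None:
            continue
        s_idx = SERVICES.index(service)
        c = arrays.costs[:, :, s_idx]
        obs = ~np.isnan(c) & arrays.valid
        if not obs.any():
            continue
        x = _service_design(arrays, tp)[obs]  # (n_obs, p)
        c_obs = c[obs]
        use_logit = x @ tp.use_coef.T            # (n_obs, L)
        pos = c_obs > 0
        contrib = np.where(pos[:, None], log_expit(use_logit), log_expit(-use_logit))
        if pos.any():
            # clip the linear predictor: keeps posteriors finite even if an
            # intermediate M-step fit ran away on a near-empty state
            mean = np.exp(np.clip(x[pos] @ tp.mean_coef.T, -30.0, 30.0))
            contrib[pos] += _gamma_logpdf(c_obs[pos][:, None], mean, tp.shape)
        logg[:, :, :L][obs] += contrib

    # death observation conventions
    logg[:, :, :L][arrays.dead] = _LOG_ZERO
    alive = arrays.valid & ~arrays.dead
    logg[:, :, L][alive] = _LOG_ZERO
    logg[~arrays.valid] = 0.0
    return logg
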