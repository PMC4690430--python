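"""EM estimation of the latent Markov health model.

`LatentHealthModel` wraps a panel and exposes `fit()`, which runs
expectation-maximisation: the E-step computes smoothed state posteriors by
forward-backward (handling years whose indicators are unobserved by letting
the cost density alone carry the emission), and the M-step re-estimates the
initial-state, transition, indicator and two-part hospital-cost parameters by
posterior-weighted maximum likelihood.  Home-care and long-term-care cost
models are fitted ex-post on their registry window, holding the posteriors
fixed.  `LatentHealthResults` carries the estimates, fit diagnostics, state
labelling and reporting operations.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.vq import kmeans2
from scipy.special import expit

from .glmfit import solve_gamma_shape, weighted_gamma_fit, weighted_softmax_fit
from .likelihood import PosteriorSet, forward_backward_batch
from .panel import PanelDataset
from .params import SERVICES, CovariateSpec, LatentModelParams, TwoPartParams
from .synthetic import BASELINE_EDUCATION, BASELINE_PARTNER

__all__ = ["LatentHealthModel", "LatentHealthResults", "select_num_states"]

STATE_NAMES = ("good", "moderate", "poor")

_MIN_STATE_WEIGHT = 1e-6


class LatentHealthModel:
    """Latent Markov model of health states, indicators and costs.

    Parameters
    ----------
    panel : PanelDataset
        Individual-year records with the observation schedule applied.
    n_states : int
        Latent states including death (default 4 = 3 living + death).
    covariates : CovariateSpec, optional
        Defaults to age centred at 75 per decade with calendar-year dummies
        spanning the panel window.
    services_in_likelihood : tuple of str
        Cost services entering the joint likelihood (default hospital only;
        the remaining services are fitted ex-post).
    """

    def __init__(
        self,
        panel: PanelDataset,
        n_states: int = 4,
        covariates: CovariateSpec | None = None,
        services_in_likelihood: tuple[str, ...] = ("hospital",),
    ) -> None:
        if n_states < 2:
            raise ValueError("need at least one living state plus death")
        if len(panel.df) == 0:
            raise ValueError("panel is empty")
        self.panel = panel
        self.scheme = panel.scheme
        self.n_states = n_states
        self.services = tuple(services_in_likelihood)
        sched = panel.schedule
        self.covariates = covariates or CovariateSpec(
            year_levels=tuple(range(sched.start_year, sched.end_year + 1))
        )
        self.arrays = panel.to_arrays(self.covariates)
        self._index_mstep_data()

    # -- pre-indexed M-step data ------------------------------------------

    def _index_mstep_data(self) -> None:
        a = self.arrays
        self._step_valid = a.valid[:, 1:]
        self._x_step = a.x_trans[:, :-1][self._step_valid]
        flat_valid = a.valid.reshape(-1)
        self._ind_obs = []
        for j in range(self.scheme.n_indicators):
            yj = a.y[:, :, j].reshape(-1)
            cells = np.flatnonzero((yj >= 0) & flat_valid)
            self._ind_obs.append((cells, yj[cells]))
        self._cost_obs = {}
        for service in self.services:
            s_i = SERVICES.index(service)
            c = a.costs[:, :, s_i].reshape(-1)
            mask = ~np.isnan(c) & flat_valid & ~a.dead.reshape(-1)
            cells = np.flatnonzero(mask)
            x = a.x_cost.reshape(-1, a.x_cost.shape[-1])[cells]
            self._cost_obs[service] = (cells, x, c[cells])

    @property
    def n_obs(self) -> int:
        return int(self.arrays.valid.sum())

    # -- EM ----------------------------------------------------------------

    def loglike(self, params: LatentModelParams) -> float:
        """Observed-data log-likelihood at the given parameters."""
        return forward_backward_batch(params, self.arrays, services=self.services).total_loglik

    def _e_step(self, params: LatentModelParams) -> PosteriorSet:
        return forward_backward_batch(params, self.arrays, services=self.services)

    def _m_step(self, post: PosteriorSet, prev: LatentModelParams) -> LatentModelParams:
        a = self.arrays
        L, M = prev.n_living, prev.n_states
        new = prev.copy()
        gamma_flat = post.gamma.reshape(-1, M)

        # initial-state logit on [1, age_c, female] at first observation
        w0 = post.gamma[:, 0, :L]
        new.init_coef = weighted_softmax_fit(a.x_init, w0, reference=0, start=prev.init_coef)

        # per-origin transition logits
        for l in range(L):
            W = post.xi[:, :, l, :][self._step_valid]
            if W.sum() < _MIN_STATE_WEIGHT * self._step_valid.sum():
                warnings.warn(
                    f"origin state {l} received near-zero posterior weight; "
                    "keeping previous transition coefficients (consider a restart)"
                )
                continue
            new.trans_coef[l] = weighted_softmax_fit(
                self._x_step, W, reference=l, start=prev.trans_coef[l]
            )

        # indicator intercepts: closed-form weighted category frequencies
        for j, (cells, cats) in enumerate(self._ind_obs):
            k = self.scheme.n_categories[j]
            g = gamma_flat[cells, :L]
            counts = np.zeros((L, k))
            for kk in range(k):
                counts[:, kk] = g[cats == kk].sum(axis=0)
            p = counts / np.maximum(counts.sum(axis=1, keepdims=True), 1e-300)
            p = np.maximum(p, 1e-12)
            new.ind_logits[j] = np.log(p) - np.log(p[:, :1])

        # two-part hospital-cost models
        for service in self.services:
            cells, X, c = self._cost_obs[service]
            g = gamma_flat[cells, :L]
            tp_prev = prev.costs[service]
            pos = c > 0
            use_coef = tp_prev.use_coef.copy()
            mean_coef = tp_prev.mean_coef.copy()
            sh_y, sh_mu, sh_w = [], [], []
            for m in range(L):
                w = g[:, m]
                if w.sum() < _MIN_STATE_WEIGHT * len(w):
                    warnings.warn(
                        f"state {m} received near-zero weight in the {service} cost "
                        "model; keeping previous coefficients"
                    )
                    continue
                W2 = np.stack([w * (~pos), w * pos], axis=1)
                start2 = np.stack([np.zeros_like(use_coef[m]), use_coef[m]])
                use_coef[m] = weighted_softmax_fit(X, W2, reference=0, start=start2)[1]
                wp = w[pos]
                keep = wp > 1e-10
                if keep.sum() >= X.shape[1]:
                    coefm, mu = weighted_gamma_fit(
                        X[pos][keep], c[pos][keep], wp[keep], start=mean_coef[m]
                    )
                    mean_coef[m] = coefm
                    sh_y.append(c[pos][keep])
                    sh_mu.append(mu)
                    sh_w.append(wp[keep])
            shape = tp_prev.shape
            if sh_y:
                shape = solve_gamma_shape(
                    np.concatenate(sh_y), np.concatenate(sh_mu), np.concatenate(sh_w)
                )
            new.costs[service] = TwoPartParams(use_coef, mean_coef, shape)
        return new

    # -- initial values ----------------------------------------------------

    def _severity_scores(self) -> np.ndarray:
        """Per-record mean standardised indicator severity, NaN-filled."""
        a = self.arrays
        num = np.zeros(a.valid.shape)
        den = np.zeros(a.valid.shape)
        for j, k in enumerate(self.scheme.n_categories):
            yj = a.y[:, :, j]
            obs = yj >= 0
            num[obs] += yj[obs] / (k - 1)
            den[obs] += 1
        with np.errstate(invalid="ignore"):
            s = num / den
        # carry an individual's nearest observed score into unobserved years
        df = pd.DataFrame(np.where(a.valid, s, np.nan))
        df = df.ffill(axis=1).bfill(axis=1)
        s = df.to_numpy()
        s[np.isnan(s)] = np.nanmean(s) if np.isfinite(np.nanmean(s)) else 0.5
        return s

    def _initial_posteriors(self, how: str, rng: np.random.Generator) -> PosteriorSet:
        a = self.arrays
        N, T = a.valid.shape
        L, M = self.n_states - 1, self.n_states
        gamma = np.zeros((N, T, M))
        alive = a.valid & ~a.dead
        if how == "kmeans":
            s = self._severity_scores()
            vals = s[alive]
            _, labels_all = kmeans2(vals.reshape(-1, 1), L, minit="++", seed=1234567)
            centroids = np.array([vals[labels_all == l].mean() if (labels_all == l).any() else np.inf for l in range(L)])
            order = np.argsort(centroids)
            rank = np.empty(L, dtype=int)
            rank[order] = np.arange(L)
            lab = rank[labels_all]
            soft = np.full((lab.size, L), 0.15 / max(L - 1, 1))
            soft[np.arange(lab.size), lab] = 0.85
            gamma[alive, :L] = soft
        elif how == "random":
            gamma[alive, :L] = rng.dirichlet(np.ones(L), size=int(alive.sum()))
        else:
            raise ValueError(f"unknown init strategy '{how}'")
        gamma[a.dead, M - 1] = 1.0
        # sticky pairwise posteriors for the transition M-step
        xi = np.zeros((N, max(T - 1, 0), M, M))
        if T > 1:
            outer = gamma[:, :-1, :, None] * gamma[:, 1:, None, :]
            boost = np.eye(M) * 3.0 + 1.0
            outer = outer * boost
            tot = outer.sum(axis=(2, 3), keepdims=True)
            step_valid = self._step_valid
            outer = np.where(step_valid[:, :, None, None] & (tot > 0), outer / np.maximum(tot, 1e-300), 0.0)
            xi = outer
        return PosteriorSet(gamma=gamma, xi=xi, loglik=np.zeros(N), ids=a.ids)

    def _start_params(self, how: str, rng: np.random.Generator) -> LatentModelParams:
        L, M = self.n_states - 1, self.n_states
        cov = self.covariates
        base = LatentModelParams(
            n_states=M,
            scheme=self.scheme,
            covariates=cov,
            init_coef=np.zeros((L, cov.n_init)),
            trans_coef=np.zeros((L, M, cov.n_trans)),
            ind_logits=[np.zeros((L, k)) for k in self.scheme.n_categories],
            costs={
                s: (
                    TwoPartParams(np.zeros((L, cov.n_cost)), np.zeros((L, cov.n_cost)), 1.0)
                    if s in self.services
                    else None
                )
                for s in SERVICES
            },
        )
        # seed the mean coefficients at the weighted log-mean cost
        for service in self.services:
            _, _, c = self._cost_obs[service]
            if (c > 0).any():
                base.costs[service].mean_coef[:, 0] = np.log(c[c > 0].mean())
        post = self._initial_posteriors(how, rng)
        return self._m_step(post, base)

    # -- public fitting API -------------------------------------------------

    def fit(
        self,
        init: str = "kmeans",
        start_params: LatentModelParams | None = None,
        tol: float = 1e-7,
        max_iter: int = 500,
        n_restarts: int = 1,
        seed: int = 0,
        verbose: bool = False,
    ) -> "LatentHealthResults":
        """Run EM to convergence.

        ``tol`` is the relative log-likelihood change that stops iteration.
        With ``n_restarts > 1``, additional random initialisations are run and
        the best final log-likelihood is kept.  ``start_params`` overrides the
        initialisation entirely (e.g. to verify stationarity at a truth).
        """
        rng = np.random.default_rng(seed)
        best: LatentHealthResults | None = None
        for r in range(max(n_restarts, 1)):
            if start_params is not None:
                p0 = start_params.copy()
            else:
                p0 = self._start_params(init if r == 0 else "random", rng)
            res = self._run_em(p0, tol, max_iter, verbose)
            res.restart_index = r
            if best is None or res.llf > best.llf:
                best = res
        best.n_restarts = max(n_restarts, 1)
        best.seed = seed
        return best

    def _run_em(self, params, tol, max_iter, verbose) -> "LatentHealthResults":
        trace = []
        converged = False
        ll_prev = -np.inf
        for it in range(max_iter):
            post = self._e_step(params)
            ll = post.total_loglik
            trace.append(ll)
            if verbose:
                print(f"EM iter {it:4d}  loglik {ll:.6f}")
            if it > 0 and abs(ll - ll_prev) < tol * max(abs(ll), 1.0):
                converged = True
                break
            new_params = self._m_step(post, params)
            ll_prev = ll
            params = new_params
        else:
            post = self._e_step(params)
            trace.append(post.total_loglik)
        return LatentHealthResults(
            model=self,
            params=params,
            llf=trace[-1],
            loglik_trace=np.asarray(trace),
            converged=converged,
            n_iter=len(trace) - 1,
        )


@dataclass
class LatentHealthResults:
    """Estimates and diagnostics of a fitted latent Markov health model."""

    model: LatentHealthModel
    params: LatentModelParams
    llf: float
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int
    n_restarts: int = 1
    restart_index: int = 0
    seed: int | None = None
    _post: PosteriorSet | None = field(default=None, repr=False)

    # -- information criteria ---------------------------------------------

    @property
    def n_params(self) -> int:
        return self.params.n_free_params(services=self.model.services)

    @property
    def aic(self) -> float:
        return 2 * self.n_params - 2 * self.llf

    @property
    def bic(self) -> float:
        return self.n_params * np.log(self.model.n_obs) - 2 * self.llf

    # -- posteriors --------------------------------------------------------

    def posteriors(self) -> PosteriorSet:
        if self._post is None:
            self._post = self.model._e_step(self.params)
        return self._post

    def posteriors_frame(self) -> pd.DataFrame:
        """Smoothed state probabilities as a tidy frame (id, year, gamma_*)."""
        post = self.posteriors()
        a = self.model.arrays
        rows = []
        for i in range(a.n_individuals):
            for t in range(int(a.valid[i].sum())):
                rows.append(
                    [a.ids[i], int(a.year[i, t])] + list(post.gamma[i, t])
                )
        cols = ["id", "year"] + [f"gamma_{m + 1}" for m in range(self.params.n_states)]
        return pd.DataFrame(rows, columns=cols)

    # -- state labelling and profiles ---------------------------------------

    def state_severity(self) -> np.ndarray:
        """Mean standardised severity per living state (0 best, 1 worst)."""
        L = self.params.n_living
        sev = np.zeros(L)
        for j, k in enumerate(self.params.scheme.n_categories):
            p = self.params.indicator_probs(j)
            sev += p @ (np.arange(k) / (k - 1))
        return sev / self.params.scheme.n_indicators

    def label_states(self) -> "LatentHealthResults":
        """Return results with living states ordered good -> poor.

        Ordering is by mean standardised severity, with the state-specific
        death probability at the reference profile (men at 75) as the
        deterministic tie-break; death stays last.  Idempotent, and the
        log-likelihood is invariant under the relabelling.
        """
        p = self.params
        L = p.n_living
        x_ref = p.covariates.trans_vector(0, BASELINE_PARTNER, 75, BASELINE_EDUCATION)
        death_prob = np.array([p.transition_row(l, x_ref)[p.death_state] for l in range(L)])
        perm = np.lexsort((death_prob, np.round(self.state_severity(), 12)))
        if np.array_equal(perm, np.arange(L)):
            return self
        new = p.copy()
        new.init_coef = p.init_coef[perm] - p.init_coef[perm][0]
        perm_full = np.concatenate([perm, [p.death_state]])
        tc = p.trans_coef[perm][:, perm_full, :]
        for l in range(L):
            tc[l] = tc[l] - tc[l, l]
        new.trans_coef = tc
        new.ind_logits = [a[perm] for a in p.ind_logits]
        for s, tp in p.costs.items():
            if tp is not None:
                new.costs[s] = TwoPartParams(
                    tp.use_coef[perm], tp.mean_coef[perm], tp.shape, tp.year_levels
                )
        return LatentHealthResults(
            model=self.model,
            params=new,
            llf=self.llf,
            loglik_trace=self.loglik_trace,
            converged=self.converged,
            n_iter=self.n_iter,
            n_restarts=self.n_restarts,
            restart_index=self.restart_index,
            seed=self.seed,
        )

    def state_profiles(self) -> pd.DataFrame:
        """Expected indicator outcome per state, standardised to [0, 1].

        0 is the best possible category, 1 the worst; rows are living states.
        """
        p = self.params
        data = {}
        for j, (name, k) in enumerate(zip(p.scheme.names, p.scheme.n_categories)):
            data[name] = p.indicator_probs(j) @ (np.arange(k) / (k - 1))
        idx = [STATE_NAMES[l] if l < len(STATE_NAMES) else f"state_{l + 1}" for l in range(p.n_living)]
        return pd.DataFrame(data, index=idx)

    def expected_cost_curve(
        self,
        state: int,
        sex: int,
        service: str,
        ages=np.arange(65, 100),
    ) -> pd.DataFrame:
        """Expected annual cost p_use(x) * mean(x) along age, other covariates
        at baseline levels and calendar-year effects at the reference level."""
        tp = self.params.costs.get(service)
        if tp is None:
            raise ValueError(f"no fitted cost model for service '{service}'")
        expected = expected_annual_cost(self.params, state, sex, np.asarray(ages), service)
        return pd.DataFrame({"age": np.asarray(ages), "expected_cost": expected})

    # -- ex-post cost models -------------------------------------------------

    def fit_expost_costs(self, service: str, n_refinements: int = 5) -> "LatentHealthResults":
        """Fit the two-part cost model of a registry-window service ex-post.

        The structural (transition, initial, indicator) and hospital-cost
        parameters stay fixed.  Starting from the converged posteriors, the
        service's two-part parameters are fitted by posterior-weighted
        likelihood on the registry window; the posteriors are then refreshed
        with the service's own emission included and the fit repeated
        (``n_refinements`` times), which sharpens the state assignment and
        removes most of the cross-state contamination a single soft-weighted
        pass suffers from.  Returns results with the parameters attached.
        """
        from .likelihood import forward_backward_batch

        new = self.params.copy()
        post = self.posteriors()
        for k in range(n_refinements + 1):
            tp = fit_expost_cost_model(self.model.panel, post, service,
                                       covariates=self.model.covariates)
            new.costs[service] = tp
            if k < n_refinements:
                post = forward_backward_batch(
                    new, self.model.arrays, services=self.model.services + (service,)
                )
        out = LatentHealthResults(
            model=self.model, params=new, llf=self.llf,
            loglik_trace=self.loglik_trace, converged=self.converged,
            n_iter=self.n_iter, n_restarts=self.n_restarts,
            restart_index=self.restart_index, seed=self.seed,
        )
        out._post = self._post
        return out

    # -- persistence ---------------------------------------------------------

    def to_json(self, path) -> None:
        doc = {
            "schema_version": 1,
            "params": self.params.to_dict(),
            "llf": self.llf,
            "loglik_trace": list(map(float, self.loglik_trace)),
            "converged": self.converged,
            "n_iter": self.n_iter,
            "n_restarts": self.n_restarts,
            "seed": self.seed,
            "n_obs": self.model.n_obs if self.model is not None else None,
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    def summary(self) -> str:
        p = self.params
        lines = [
            "Latent Markov health model",
            "=" * 60,
            f"states (incl. death): {p.n_states}    individuals: {self.model.arrays.n_individuals}",
            f"records: {self.model.n_obs}    free parameters: {self.n_params}",
            f"log-likelihood: {self.llf:.3f}   AIC: {self.aic:.1f}   BIC: {self.bic:.1f}",
            f"EM iterations: {self.n_iter}   converged: {self.converged}",
            "",
            "Standardised state profiles (0 best, 1 worst):",
            self.state_profiles().round(3).to_string(),
            "",
            "Transition matrix, men at 75 (reference profile):",
        ]
        x_ref = p.covariates.trans_vector(0, BASELINE_PARTNER, 75, BASELINE_EDUCATION)
        P = p.transition_matrix(x_ref)
        names = list(STATE_NAMES[: p.n_living]) + ["death"]
        lines.append(pd.DataFrame(P, index=names, columns=names).round(3).to_string())
        return "\n".join(lines)


def expected_annual_cost(
    params: LatentModelParams,
    state: int,
    sex: int,
    age,
    service: str,
    partner: int = BASELINE_PARTNER,
    education: int = BASELINE_EDUCATION,
) -> np.ndarray:
    """Two-part expected annual cost for one living state along age."""
    tp = params.costs.get(service)
    if tp is None:
        raise ValueError(f"no fitted cost model for service '{service}'")
    n_base = params.covariates.n_trans
    x = params.covariates.trans_vector(sex, partner, age, education)
    n_extra = tp.use_coef.shape[1] - n_base
    if n_extra > 0:
        x = np.concatenate([x, np.zeros(x.shape[:-1] + (n_extra,))], axis=-1)
    p_use = expit(x @ tp.use_coef[state])
    mean = np.exp(x @ tp.mean_coef[state])
    return p_use * mean


def fit_expost_cost_model(
    panel: PanelDataset,
    posteriors: PosteriorSet,
    service: str,
    covariates: CovariateSpec,
) -> TwoPartParams:
    """Posterior-weighted two-part fit for a service observed in a window.

    Calendar-year dummies span the window years only (reference = first
    window year).
    """
    window = panel.schedule.registry_windows.get(service)
    if window is None:
        raise ValueError(f"panel schedule has no registry window for '{service}'")
    arrays = panel.to_arrays(covariates)
    s_i = SERVICES.index(service)
    c = arrays.costs[:, :, s_i]
    in_window = (arrays.year >= window[0]) & (arrays.year <= window[1])
    mask = ~np.isnan(c) & arrays.valid & ~arrays.dead & in_window
    if not mask.any():
        raise ValueError(f"no observed {service} costs inside window {window}")
    win_years = tuple(range(window[0], window[1] + 1))
    win_cov = CovariateSpec(
        age_center=covariates.age_center,
        age_scale=covariates.age_scale,
        year_levels=win_years,
    )
    # rebuild the design with window-year dummies
    base = arrays.x_trans[mask]  # [1, female, partner, age_c, edu_mid, edu_high]
    years = arrays.year[mask]
    dums = np.stack([(years == y).astype(float) for y in win_years[1:]], axis=1) if len(win_years) > 1 else np.zeros((mask.sum(), 0))
    X = np.concatenate([base, dums], axis=1)
    cvals = c[mask]
    pos = cvals > 0
    L = posteriors.gamma.shape[2] - 1
    g = posteriors.gamma[mask][:, :L]
    p = X.shape[1]
    use_coef = np.zeros((L, p))
    mean_coef = np.zeros((L, p))
    sh_y, sh_mu, sh_w = [], [], []
    global_log_mean = float(np.log(cvals[pos].mean())) if pos.any() else 0.0
    for m in range(L):
        w = g[:, m]
        W2 = np.stack([w * (~pos), w * pos], axis=1)
        use_coef[m] = weighted_softmax_fit(X, W2, reference=0)[1]
        wp = w[pos]
        keep = wp > 1e-10
        if keep.sum() < p:
            # sparse state: fall back to an intercept-only positive-cost mean
            warnings.warn(
                f"only {int(keep.sum())} positive {service} observations carry "
                f"state-{m} weight in window {window}; intercept-only mean fitted"
            )
            mean_coef[m] = 0.0
            if keep.any():
                mean_coef[m, 0] = float(
                    np.log(np.average(cvals[pos][keep], weights=wp[keep]))
                )
            else:
                mean_coef[m, 0] = global_log_mean
            continue
        mean_coef[m], mu = weighted_gamma_fit(X[pos][keep], cvals[pos][keep], wp[keep])
        sh_y.append(cvals[pos][keep])
        sh_mu.append(mu)
        sh_w.append(wp[keep])
    if not sh_y:
        raise ValueError(f"no state has enough positive {service} observations in window {window}")
    shape = solve_gamma_shape(np.concatenate(sh_y), np.concatenate(sh_mu), np.concatenate(sh_w))
    return TwoPartParams(use_coef, mean_coef, shape, year_levels=win_years)


def select_num_states(
    panel: PanelDataset,
    candidate_states=(3, 4, 5),
    **fit_kwargs,
) -> pd.DataFrame:
    """Fit the model for several state counts and compare information criteria.

    Returns a table (one row per candidate M, death included) with
    log-likelihood, parameter count, AIC and BIC; the BIC-minimal converged
    candidate is flagged.  Non-converged candidates are flagged, not
    silently compared.
    """
    rows = []
    for M in candidate_states:
        res = LatentHealthModel(panel, n_states=M).fit(**fit_kwargs)
        rows.append(
            {
                "n_states": M,
                "loglik": res.llf,
                "n_params": res.n_params,
                "aic": res.aic,
                "bic": res.bic,
                "converged": res.converged,
            }
        )
        if not res.converged:
            warnings.warn(f"candidate M={M} did not converge; flagged in the table")
    table = pd.DataFrame(rows)
    conv = table[table["converged"]]
    table["bic_best"] = False
    if not conv.empty:
        table.loc[conv["bic"].idxmin(), "bic_best"] = True
    return table
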