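"""Seeded synthetic panels with the structure of a linked survey-registry sample.

The generator emulates an individual-year panel of Dutch-style older adults:
entry ages 55-85 at the 1995 panel start plus a refreshment cohort of
55-64-year-olds in 2002, seven categorical health indicators observed every
third year, annual hospital costs, home-care and institutional long-term-care
costs observed only in a 2004-2007 registry window, and death as an absorbing
state.  Attrition other than death is not simulated.

The default ground truth anchors its demographic core to published Dutch
quantities: the baseline transition matrix for men at 75 (good row
0.87/0.07/0.04/0.02) and the baseline health profile at 65 (0.66/0.27/0.06
over living states); death-logit age and sex effects are fixed at
demographically plausible values (mortality odds doubling per decade, a
female survival advantage), giving baseline remaining life expectancies at
65 close to Dutch values over the emulated 1995-2007 window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .panel import (
    VITAL_ALIVE,
    VITAL_DIED,
    ObservationSchedule,
    PanelDataset,
    apply_observation_schedule,
)
from .params import (
    SERVICES,
    CovariateSpec,
    IndicatorScheme,
    LatentModelParams,
    TwoPartParams,
    default_indicator_scheme,
)

__all__ = [
    "CovariateProfile",
    "PanelDesign",
    "make_default_truth",
    "simulate_individual",
    "simulate_panel",
]

#: Reference covariate levels ("baseline characteristics"): partnered, low education.
BASELINE_PARTNER = 1
BASELINE_EDUCATION = 0

# Baseline annual transition rows for men at 75 (good/moderate/poor x
# good/moderate/poor/death).  The zero cells of the printed matrix are
# replaced by small positive values a multinomial logit can represent.
_ANCHOR_ROWS = np.array(
    [
        [0.870, 0.070, 0.040, 0.020],
        [0.005, 0.865, 0.100, 0.030],
        [0.002, 0.040, 0.808, 0.150],
    ]
)

# Baseline living-state shares at 65 for men (renormalised 0.66/0.27/0.06).
_ANCHOR_INIT = np.array([0.66, 0.27, 0.06]) / 0.99

# Death-logit age slope (mortality odds roughly double per decade) and the
# female shift (sex gap in old-age mortality).  Together with the anchored
# rows these give baseline remaining LE at 65 of about 15.0 years for men
# and 18.7 for women -- in line with the Netherlands over the emulated
# 1995-2007 estimation window.
_DEATH_AGE_SLOPE = 0.69
_FEMALE_DEATH_SHIFT = -0.50

# Standardised severity (0 best, 1 worst) per indicator for good/moderate/poor.
_SEVERITY = {
    "self_perceived_health": (0.15, 0.45, 0.55),
    "mobility": (0.05, 0.35, 0.75),
    "performance": (0.08, 0.40, 0.80),
    "gali": (0.08, 0.45, 0.80),
    "chronic_diseases": (0.20, 0.70, 0.85),
    "depression": (0.05, 0.15, 0.55),
    "cognition": (0.03, 0.12, 0.60),
}

# Two-part cost anchors at the reference profile (men, 75, partnered, low
# education): use probability and mean positive cost per state, plus shape.
_COST_ANCHORS = {
    "hospital": {"p_use": (0.12, 0.35, 0.50), "mean": (3000.0, 6000.0, 9000.0), "shape": 1.2},
    "homecare": {"p_use": (0.03, 0.18, 0.45), "mean": (2000.0, 4500.0, 8000.0), "shape": 0.9},
    "ltc": {"p_use": (0.004, 0.04, 0.30), "mean": (9000.0, 15000.0, 30000.0), "shape": 1.5},
}

# Non-intercept covariate effects on cost logits/log-means:
# (female, partner, age_c, edu_mid, edu_high)
_COST_SLOPES = {
    "hospital": {"use": (-0.05, 0.0, 0.35, -0.05, -0.10), "mean": (-0.05, 0.0, 0.15, -0.05, -0.10)},
    "homecare": {"use": (0.40, -0.50, 0.80, -0.10, -0.20), "mean": (0.10, -0.20, 0.30, 0.0, 0.0)},
    "ltc": {"use": (0.30, -0.60, 1.00, -0.10, -0.20), "mean": (0.0, 0.0, 0.20, 0.0, 0.0)},
}


@dataclass(frozen=True)
class CovariateProfile:
    """Covariates of one simulated individual at entry."""

    sex: int  # 0 male, 1 female
    partner_status: int
    age: int
    education_level: int  # 0 low, 1 mid, 2 high
    calendar_year: int

    def validate(self, year_range: tuple[int, int] | None = None) -> None:
        if self.sex not in (0, 1):
            raise ValueError(f"sex must be 0 or 1, got {self.sex}")
        if self.partner_status not in (0, 1):
            raise ValueError(f"partner_status must be 0 or 1, got {self.partner_status}")
        if not 55 <= self.age <= 110:
            raise ValueError(f"entry age must lie in [55, 110], got {self.age}")
        if self.education_level not in (0, 1, 2):
            raise ValueError(f"education_level must be 0, 1 or 2, got {self.education_level}")
        if year_range is not None and not year_range[0] <= self.calendar_year <= year_range[1]:
            raise ValueError(
                f"calendar_year {self.calendar_year} outside window {year_range}"
            )


@dataclass(frozen=True)
class PanelDesign:
    """Sampling design of a synthetic panel.

    Defaults mirror the emulated study: a 1995-2007 window, entry ages
    uniform on 55-85, tri-annual health interviews, a 2002 refreshment
    cohort of 55-64-year-olds sized like the original one (about 24% of all
    respondents), annual hospital costs and a 2004-2007 long-term-care and
    home-care registry window.
    """

    start_year: int = 1995
    n_years: int = 13
    survey_interval: int = 3
    entry_age_range: tuple[int, int] = (55, 85)
    refresh_year: int | None = 2002
    refresh_fraction: float = 1002 / 4109
    refresh_age_range: tuple[int, int] = (55, 64)
    registry_windows: dict[str, tuple[int, int]] | None = None
    female_share: float = 0.5
    education_probs: tuple[float, float, float] = (0.4, 0.4, 0.2)
    widowhood_hazard: float = 0.03

    @property
    def end_year(self) -> int:
        return self.start_year + self.n_years - 1

    @property
    def windows(self) -> dict[str, tuple[int, int]]:
        """Per-service registry windows; by default hospital costs span the
        whole panel while home-care/LTC cover only the last four years."""
        if self.registry_windows is not None:
            return self.registry_windows
        late = (max(self.start_year, self.end_year - 3), self.end_year)
        return {"hospital": (self.start_year, self.end_year), "homecare": late, "ltc": late}

    def covariate_spec(self) -> CovariateSpec:
        return CovariateSpec(year_levels=tuple(range(self.start_year, self.end_year + 1)))


# ---------------------------------------------------------------------------
# default ground truth
# ---------------------------------------------------------------------------


def _life_expectancy_at(params: LatentModelParams, sex: int, entry_age: int = 65,
                        age_cap: int = 110) -> float:
    """Baseline remaining LE with start-of-year occupancy + half-year death credit."""
    cov = params.covariates
    L = params.n_living
    occ = params.initial_probs(cov.init_vector(entry_age, sex))
    le = 0.0
    for age in range(entry_age, age_cap):
        P = params.transition_matrix(
            cov.trans_vector(sex, BASELINE_PARTNER, age, BASELINE_EDUCATION)
        )
        le += occ.sum() - 0.5 * float(occ @ P[:L, -1])
        occ = occ @ P[:L, :L]
    return le


def _severity_logits(s: float, k: int) -> np.ndarray:
    """Binomial-shaped category logits with standardised expected severity s."""
    kk = np.arange(k)
    return np.array([math.lgamma(k) - math.lgamma(j + 1) - math.lgamma(k - j) for j in kk]) + (
        kk * (np.log(s) - np.log1p(-s))
    )


def make_default_truth(
    seed: int = 1,
    scheme: IndicatorScheme | None = None,
    design: PanelDesign | None = None,
) -> LatentModelParams:
    """Ground-truth parameter set with 3 living states + death.

    State 1 dominates state 2 dominates state 3 in expected severity on all
    seven indicators; death hazards rise from state 1 to 3; the demographic
    core (anchored transition rows, initial shares, death-logit slopes) is
    identical across seeds, while indicator and cost anchors carry a small
    seeded jitter.
    """
    rng = np.random.default_rng(seed)
    scheme = scheme or default_indicator_scheme()
    design = design or PanelDesign()
    cov = design.covariate_spec()
    L, M = 3, 4

    # --- transition block ------------------------------------------------
    # covariate effects (female, partner, age_c, edu_mid, edu_high) on the
    # destination logits; the death-column age slope and female shift are
    # calibrated below.
    def build_trans(s_death: float, female_death: float) -> np.ndarray:
        coef = np.zeros((L, M, cov.n_trans))
        for l in range(L):
            for m in range(M):
                if m == l:
                    continue
                if m == M - 1:  # death
                    coef[l, m, 1] = female_death
                    coef[l, m, 2] = -0.15      # partner
                    coef[l, m, 3] = s_death    # age per decade
                    coef[l, m, 4] = -0.08
                    coef[l, m, 5] = -0.15
                elif m > l:     # worse living state
                    coef[l, m, 3] = 0.35
                    coef[l, m, 4] = -0.08
                    coef[l, m, 5] = -0.15
                else:           # recovery
                    coef[l, m, 3] = -0.25
                    coef[l, m, 4] = 0.05
                    coef[l, m, 5] = 0.10
                # intercept anchors the row at the reference profile
                # (male, partnered, low education, age 75)
                coef[l, m, 0] = np.log(_ANCHOR_ROWS[l, m] / _ANCHOR_ROWS[l, l]) - coef[l, m, 2]
        return coef

    # initial-state block (anchored at men aged 65)
    init_coef = np.zeros((L, cov.n_init))
    init_age_slope = np.array([0.0, 0.45, 0.90])
    init_female = np.array([0.0, 0.15, 0.25])
    for m in range(1, L):
        init_coef[m, 1] = init_age_slope[m]
        init_coef[m, 2] = init_female[m]
        init_coef[m, 0] = np.log(_ANCHOR_INIT[m] / _ANCHOR_INIT[0]) + init_age_slope[m]

    # indicator block with seeded jitter on the severity anchors
    ind_logits = []
    for name, k in zip(scheme.names, scheme.n_categories):
        sev = np.array(_SEVERITY[name])
        sev = np.clip(sev + rng.uniform(-0.02, 0.02, size=3), 0.01, 0.99)
        sev.sort()  # guard the good < moderate < poor ordering
        ind_logits.append(np.stack([_severity_logits(s, k) for s in sev]))

    # cost block with seeded jitter on the anchors
    costs: dict[str, TwoPartParams] = {}
    for service in SERVICES:
        anchor = _COST_ANCHORS[service]
        slopes = _COST_SLOPES[service]
        use_coef = np.zeros((L, cov.n_cost))
        mean_coef = np.zeros((L, cov.n_cost))
        for m in range(L):
            use_coef[m, 1:6] = slopes["use"]
            mean_coef[m, 1:6] = slopes["mean"]
            p = float(np.clip(expit(logit(anchor["p_use"][m]) + rng.uniform(-0.05, 0.05)), 1e-4, 1 - 1e-4))
            mu = anchor["mean"][m] * float(np.exp(rng.uniform(-0.03, 0.03)))
            use_coef[m, 0] = logit(p) - slopes["use"][1] * BASELINE_PARTNER
            mean_coef[m, 0] = np.log(mu) - slopes["mean"][1] * BASELINE_PARTNER
        costs[service] = TwoPartParams(use_coef, mean_coef, anchor["shape"])

    def assemble(s_death: float, female_death: float) -> LatentModelParams:
        return LatentModelParams(
            n_states=M,
            scheme=scheme,
            covariates=cov,
            init_coef=init_coef,
            trans_coef=build_trans(s_death, female_death),
            ind_logits=ind_logits,
            costs=dict(costs),
        )

    return assemble(_DEATH_AGE_SLOPE, _FEMALE_DEATH_SHIFT)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def _draw_categorical(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """Vectorised categorical draw; probs (n, K) rows summing to 1."""
    u = rng.random(probs.shape[0])
    return (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)


def _simulate_cohort(
    params: LatentModelParams,
    rng: np.random.Generator,
    ids: np.ndarray,
    entry_year: int,
    end_year: int,
    sex: np.ndarray,
    partner: np.ndarray,
    age: np.ndarray,
    education: np.ndarray,
    widowhood_hazard: float,
    latent_rows: list | None = None,
) -> list[dict]:
    """Simulate one entry cohort year by year; returns record dicts."""
    cov = params.covariates
    L = params.n_living
    n = len(ids)
    if n == 0:
        return []
    state = _draw_categorical(rng, params.initial_probs(cov.init_vector(age, sex)))
    alive = np.ones(n, dtype=bool)
    records: list[dict] = []

    sex = sex.astype(int).copy()
    partner = partner.astype(int).copy()
    age = age.astype(int).copy()
    education = education.astype(int).copy()

    for year in range(entry_year, end_year + 1):
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        st = state[idx]
        # indicators
        ymat = np.empty((idx.size, params.scheme.n_indicators), dtype=int)
        for j in range(params.scheme.n_indicators):
            ymat[:, j] = _draw_categorical(rng, params.indicator_probs(j)[st])
        # two-part costs
        x_cost = cov.cost_vector(sex[idx], partner[idx], age[idx], education[idx], year)
        cmat = np.zeros((idx.size, len(SERVICES)))
        for s_i, service in enumerate(SERVICES):
            tp = params.costs[service]
            p_use = expit(np.einsum("np,np->n", x_cost, tp.use_coef[st]))
            mean = np.exp(np.einsum("np,np->n", x_cost, tp.mean_coef[st]))
            use = rng.random(idx.size) < p_use
            draw = rng.gamma(tp.shape, mean / tp.shape)
            cmat[:, s_i] = np.where(use, draw, 0.0)
        for r, i in enumerate(idx):
            rec = {
                "id": ids[i], "year": year, "sex": sex[i], "partner": partner[i],
                "age": age[i], "education": education[i], "vital_status": VITAL_ALIVE,
            }
            for j in range(params.scheme.n_indicators):
                rec[f"y{j + 1}"] = ymat[r, j]
            for s_i, service in enumerate(SERVICES):
                rec[f"cost_{service}"] = round(float(cmat[r, s_i]), 2)
            records.append(rec)
            if latent_rows is not None:
                latent_rows.append({"id": ids[i], "year": year, "state": int(st[r])})
        if year == end_year:
            break
        # annual transition
        x_trans = cov.trans_vector(sex[idx], partner[idx], age[idx], education[idx])
        rows = params.transition_matrix(x_trans)[np.arange(idx.size), st]
        nxt = _draw_categorical(rng, rows)
        died = nxt == params.death_state
        for r, i in enumerate(idx[died]):
            records.append(
                {
                    "id": ids[i], "year": year + 1, "sex": sex[i], "partner": partner[i],
                    "age": age[i] + 1, "education": education[i], "vital_status": VITAL_DIED,
                    **{f"y{j + 1}": pd.NA for j in range(params.scheme.n_indicators)},
                    **{f"cost_{s}": np.nan for s in SERVICES},
                }
            )
            if latent_rows is not None:
                latent_rows.append({"id": ids[i], "year": year + 1, "state": params.death_state})
        state[idx] = nxt
        alive[idx[died]] = False
        # ageing and partner dynamics
        widowed = (partner == 1) & (rng.random(n) < widowhood_hazard)
        partner[widowed & alive] = 0
        age[alive] += 1
    return records


def simulate_individual(
    params: LatentModelParams,
    profile: CovariateProfile,
    horizon: int,
    rng: np.random.Generator,
    widowhood_hazard: float = 0.0,
) -> pd.DataFrame:
    """Simulate one individual's records over ``horizon`` years (fewer if death).

    The latent path starts from the initial-state model at the entry profile
    and evolves by the annual transition logits; emissions are drawn from the
    state's indicator logits and two-part cost models.  Records stop at the
    death-year record.
    """
    if horizon < 1:
        raise ValueError("horizon must be at least 1")
    profile.validate()
    records = _simulate_cohort(
        params,
        rng,
        ids=np.array([0]),
        entry_year=profile.calendar_year,
        end_year=profile.calendar_year + horizon - 1,
        sex=np.array([profile.sex]),
        partner=np.array([profile.partner_status]),
        age=np.array([profile.age]),
        education=np.array([profile.education_level]),
        widowhood_hazard=widowhood_hazard,
    )
    return pd.DataFrame.from_records(records)


def simulate_panel(
    params: LatentModelParams,
    n: int,
    design: PanelDesign | None = None,
    seed: int = 0,
    keep_latent: bool = False,
):
    """Simulate a full observable panel of ``n`` individuals.

    Entry ages are uniform over the design's range at the panel start; a
    refreshment cohort enters in ``design.refresh_year``.  The observation
    schedule (tri-annual indicators, per-service registry windows) is applied
    before returning, so latent states and off-schedule emissions are never
    part of the result.  With ``keep_latent=True`` a second frame with the
    true state paths is returned for testing.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    design = design or PanelDesign()
    rng = np.random.default_rng(seed)
    latent_rows: list | None = [] if keep_latent else None

    n_refresh = 0
    if design.refresh_year is not None and n > 0:
        n_refresh = int(round(n * design.refresh_fraction))
    n_init = n - n_refresh

    records: list[dict] = []
    for n_coh, entry_year, age_range, id0 in (
        (n_init, design.start_year, design.entry_age_range, 0),
        (n_refresh, design.refresh_year, design.refresh_age_range, n_init),
    ):
        if n_coh <= 0:
            continue
        ids = np.arange(id0, id0 + n_coh)
        age = rng.integers(age_range[0], age_range[1] + 1, size=n_coh)
        sex = (rng.random(n_coh) < design.female_share).astype(int)
        partner = (rng.random(n_coh) < expit(1.1 - 0.85 * (age - 65) / 10.0)).astype(int)
        education = _draw_categorical(
            rng, np.tile(np.asarray(design.education_probs), (n_coh, 1))
        )
        records.extend(
            _simulate_cohort(
                params, rng, ids, entry_year, design.end_year,
                sex, partner, age, education, design.widowhood_hazard,
                latent_rows=latent_rows,
            )
        )

    columns = (
        ["id", "year", "sex", "partner", "age", "education"]
        + [f"y{j + 1}" for j in range(params.scheme.n_indicators)]
        + [f"cost_{s}" for s in SERVICES]
        + ["vital_status"]
    )
    df = pd.DataFrame.from_records(records, columns=columns)
    full_schedule = ObservationSchedule(
        start_year=design.start_year,
        end_year=design.end_year,
        survey_years=tuple(range(design.start_year, design.end_year + 1)),
        registry_windows={s: (design.start_year, design.end_year) for s in SERVICES},
    )
    panel = PanelDataset(df, full_schedule, scheme=params.scheme)
    panel = apply_observation_schedule(panel, design.survey_interval, design.windows)
    if keep_latent:
        return panel, pd.DataFrame.from_records(latent_rows, columns=["id", "year", "state"])
    return panel
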