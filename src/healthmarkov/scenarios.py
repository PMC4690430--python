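"""Morbidity scenarios: transition adjustments, life tables, calibration.

Three hypotheses about how future life-expectancy gains arise are encoded as
operators on the annual transition rows of the fitted model:

* expansion of morbidity -- death probabilities fall in every health state by
  the same annual proportion; survivors stay in their current state;
* compression of morbidity -- transitions from good/moderate health to any
  strictly worse outcome (including death) fall, in favour of remaining in
  the current state; the poor-health row is untouched;
* dynamic equilibrium -- transitions from good/moderate health to poor
  health and death fall in favour of moderate health, while a separate rate
  reduces dying out of poor health so that expected years in poor health can
  be held at their baseline value.

Each non-baseline scenario's annual rate(s) are calibrated numerically so
that remaining life expectancy at 65 in 2050 (period life table) hits a
forecast target; scenarios with an initial-health ramp additionally move the
entrant profile at 65 linearly between its 2010 value and a 2050 endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .params import LatentModelParams
from .synthetic import BASELINE_EDUCATION, BASELINE_PARTNER

__all__ = [
    "ScenarioSpec",
    "ScenarioModel",
    "LifeTableResult",
    "scenario_catalog",
    "compound_factor",
    "apply_expansion",
    "apply_compression",
    "apply_dynamic",
    "initial_profile",
    "baseline_profile_at_65",
    "remaining_life_expectancy",
    "calibrate",
    "calibrate_all",
]

SEX_NAMES = {0: "male", 1: "female"}

#: Forecast remaining life expectancy at 65 in 2050, by sex.
STANDARD_LE_TARGETS = {0: 21.1, 1: 24.6}
OPTIMISTIC_LE_TARGETS = {0: 24.1, 1: 27.6}

GOOD, MODERATE, POOR = 0, 1, 2


@dataclass
class ScenarioSpec:
    """Identity and calibrated rates of one scenario.

    ``rates`` and ``poor_death_rates`` map sex (0 men, 1 women) to the
    calibrated annual proportional reduction; dynamic scenarios carry both.
    """

    id: str
    hypothesis: str  # baseline | expansion | compression | dynamic
    uses_initial_ramp: bool = False
    ramp_state: int | None = None
    ramp_endpoint: float | None = None
    le_targets: dict[int, float] = field(default_factory=dict)
    rates: dict[int, float] = field(default_factory=dict)
    poor_death_rates: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.hypothesis not in ("baseline", "expansion", "compression", "dynamic"):
            raise ValueError(f"unknown hypothesis '{self.hypothesis}'")
        if self.hypothesis == "baseline" and (self.le_targets or self.rates):
            raise ValueError("the baseline scenario has no targets and no rates")
        for d in (self.rates, self.poor_death_rates):
            for x in d.values():
                if not 0.0 <= x < 1.0:
                    raise ValueError("annual rates must lie in [0, 1)")
        if self.poor_death_rates and self.hypothesis != "dynamic":
            raise ValueError("only dynamic scenarios carry a poor-death rate")

    def calibrated_for(self, sex: int) -> bool:
        if self.hypothesis == "baseline":
            return True
        if sex not in self.rates:
            return False
        return self.hypothesis != "dynamic" or sex in self.poor_death_rates


def scenario_catalog() -> dict[str, ScenarioSpec]:
    """The baseline plus the eight sub-scenarios (1o/1++, 2o/2+/2++, 3o/3+/3++)."""
    return {
        "baseline": ScenarioSpec("baseline", "baseline"),
        "1o": ScenarioSpec("1o", "expansion", le_targets=dict(STANDARD_LE_TARGETS)),
        "1++": ScenarioSpec("1++", "expansion", le_targets=dict(OPTIMISTIC_LE_TARGETS)),
        "2o": ScenarioSpec("2o", "compression", le_targets=dict(STANDARD_LE_TARGETS)),
        "2+": ScenarioSpec(
            "2+", "compression", uses_initial_ramp=True, ramp_state=GOOD,
            ramp_endpoint=1.0, le_targets=dict(STANDARD_LE_TARGETS),
        ),
        "2++": ScenarioSpec(
            "2++", "compression", uses_initial_ramp=True, ramp_state=GOOD,
            ramp_endpoint=1.0, le_targets=dict(OPTIMISTIC_LE_TARGETS),
        ),
        "3o": ScenarioSpec("3o", "dynamic", le_targets=dict(STANDARD_LE_TARGETS)),
        "3+": ScenarioSpec(
            "3+", "dynamic", uses_initial_ramp=True, ramp_state=MODERATE,
            ramp_endpoint=0.45, le_targets=dict(STANDARD_LE_TARGETS),
        ),
        "3++": ScenarioSpec(
            "3++", "dynamic", uses_initial_ramp=True, ramp_state=MODERATE,
            ramp_endpoint=0.45, le_targets=dict(OPTIMISTIC_LE_TARGETS),
        ),
    }


# ---------------------------------------------------------------------------
# adjustment operators
# ---------------------------------------------------------------------------


def compound_factor(x: float, year: int, base_year: int = 2010) -> float:
    """Cumulative multiplier (1 - x)^(year - base_year) of an annual rate x."""
    if not 0.0 <= x < 1.0:
        raise ValueError("annual rate must lie in [0, 1)")
    if year < base_year:
        raise ValueError("year must not precede the base year")
    return (1.0 - x) ** (year - base_year)


def _check_row(row: np.ndarray) -> np.ndarray:
    row = np.asarray(row, dtype=float)
    if row.ndim != 1 or abs(row.sum() - 1.0) > 1e-9 or (row < -1e-15).any():
        raise ValueError("input is not a stochastic probability row")
    return row


def apply_expansion(row: np.ndarray, origin: int, multiplier: float) -> np.ndarray:
    """Scale the death entry; the freed mass stays in the current state.

    Only the death entry and the own-state (diagonal) entry change.
    """
    row = _check_row(row)
    if not 0.0 < multiplier <= 1.0:
        raise ValueError("multiplier must lie in (0, 1]")
    out = row.copy()
    freed = out[-1] * (1.0 - multiplier)
    out[-1] -= freed
    out[origin] += freed
    return out


def apply_compression(row: np.ndarray, origin: int, multiplier: float) -> np.ndarray:
    """Scale transitions to strictly worse living states and death; the freed
    mass goes to the diagonal.  The poor-origin row is returned unchanged."""
    row = _check_row(row)
    out = row.copy()
    if origin == POOR:
        return out
    worse = list(range(origin + 1, len(row)))
    freed = (out[worse] * (1.0 - multiplier)).sum()
    out[worse] *= multiplier
    out[origin] += freed
    return out


def apply_dynamic(
    row: np.ndarray, origin: int, multiplier_main: float, multiplier_poor_death: float
) -> np.ndarray:
    """Good/moderate: scale poor and death entries, freed mass to moderate;
    poor: scale the death entry, freed mass stays in poor."""
    row = _check_row(row)
    out = row.copy()
    death = len(row) - 1
    if origin == POOR:
        freed = out[death] * (1.0 - multiplier_poor_death)
        out[death] -= freed
        out[POOR] += freed
        return out
    freed = (out[[POOR, death]] * (1.0 - multiplier_main)).sum()
    out[POOR] *= multiplier_main
    out[death] *= multiplier_main
    out[MODERATE] += freed
    return out


def initial_profile(
    spec: ScenarioSpec, year: int, sex: int, baseline_profile_at_65: np.ndarray
) -> np.ndarray:
    """Entrant health profile at 65 in a given year, over living states.

    Scenarios with a ramp interpolate the targeted share linearly between its
    2010 value and the 2050 endpoint, scaling the other living states
    proportionally; all other scenarios return the 2010 profile unchanged.
    """
    base = np.asarray(baseline_profile_at_65, dtype=float)
    if abs(base.sum() - 1.0) > 1e-9:
        raise ValueError("baseline profile must sum to 1 over living states")
    if not 2010 <= year <= 2050:
        raise ValueError("year must lie in [2010, 2050]")
    if not spec.uses_initial_ramp or year <= 2010:
        return base.copy()
    frac = (year - 2010) / 40.0
    s0 = base[spec.ramp_state]
    s_t = s0 + frac * (spec.ramp_endpoint - s0)
    out = base * ((1.0 - s_t) / (1.0 - s0))
    out[spec.ramp_state] = s_t
    return out


def baseline_profile_at_65(params: LatentModelParams, sex: int) -> np.ndarray:
    """2010 living-state shares of new 65-year-olds from the initial-state model."""
    return params.initial_probs(params.covariates.init_vector(65, sex))


# ---------------------------------------------------------------------------
# the adjusted transition model and its life table
# ---------------------------------------------------------------------------


@dataclass
class LifeTableResult:
    """State-decomposed remaining life expectancy."""

    total: float
    by_state: np.ndarray
    sex: int
    entry_age: int
    year: int
    scenario_id: str

    def __post_init__(self) -> None:
        self.by_state = np.asarray(self.by_state, dtype=float)
        if (self.by_state < -1e-12).any():
            raise ValueError("per-state expected years must be non-negative")
        if abs(self.by_state.sum() - self.total) > 1e-9 * max(1.0, abs(self.total)):
            raise ValueError("per-state years must sum to the total")


@dataclass
class ScenarioModel:
    """A fitted transition model under a scenario's annual adjustments.

    At calendar year ``base_year`` (2010) the model reproduces the unadjusted
    transition rows exactly.  Transition covariates other than age and sex are
    fixed at representative values (partnered, low education by default).
    """

    params: LatentModelParams
    spec: ScenarioSpec
    base_year: int = 2010
    partner: int = BASELINE_PARTNER
    education: int = BASELINE_EDUCATION
    age_cap: int = 110
    half_year_correction: bool = True

    def baseline_matrix(self, sex: int, age: float) -> np.ndarray:
        x = self.params.covariates.trans_vector(sex, self.partner, age, self.education)
        return self.params.transition_matrix(x)

    def transition_matrix(self, sex: int, age: float, year: int) -> np.ndarray:
        """Scenario-adjusted M x M matrix for the given age, sex and year."""
        P = self.baseline_matrix(sex, age)
        spec = self.spec
        if spec.hypothesis == "baseline" or year <= self.base_year:
            return P
        if sex not in spec.rates:
            raise ValueError(
                f"scenario '{spec.id}' is not calibrated for sex {sex}"
            )
        f = compound_factor(spec.rates[sex], year, self.base_year)
        if spec.hypothesis == "expansion":
            for l in (GOOD, MODERATE, POOR):
                P[l] = apply_expansion(P[l], l, f)
        elif spec.hypothesis == "compression":
            for l in (GOOD, MODERATE):
                P[l] = apply_compression(P[l], l, f)
        else:  # dynamic
            f_pd = compound_factor(spec.poor_death_rates[sex], year, self.base_year)
            for l in (GOOD, MODERATE):
                P[l] = apply_dynamic(P[l], l, f, f_pd)
            P[POOR] = apply_dynamic(P[POOR], POOR, f, f_pd)
        return P

    def transition_row(self, origin: int, sex: int, age: float, year: int) -> np.ndarray:
        if origin == self.params.death_state:
            row = np.zeros(self.params.n_states)
            row[-1] = 1.0
            return row
        return self.transition_matrix(sex, age, year)[origin]

    def initial_profile(self, year: int, sex: int) -> np.ndarray:
        # ramps hold their endpoint values outside the 2010-2050 study window
        year = min(max(year, 2010), 2050)
        return initial_profile(self.spec, year, sex, baseline_profile_at_65(self.params, sex))

    # -- period life table -------------------------------------------------

    def life_table(self, sex: int, year: int, entry_age: int = 65) -> LifeTableResult:
        """Remaining LE at entry age under the period convention.

        Transition rates are frozen at the stated calendar year's adjusted
        values while the synthetic cohort ages; per-state years sum
        start-of-year occupancies with a half-year credit in the year of
        death; ages are capped at ``age_cap``.
        """
        L = self.params.n_living
        occ = self.initial_profile(year, sex)
        years = np.zeros(L)
        half = 0.5 if self.half_year_correction else 0.0
        for age in range(entry_age, self.age_cap):
            P = self.transition_matrix(sex, age, year)
            p_death = P[:L, -1]
            years += occ * (1.0 - half * p_death)
            occ = occ @ P[:L, :L]
        return LifeTableResult(
            total=float(years.sum()),
            by_state=years,
            sex=sex,
            entry_age=entry_age,
            year=year,
            scenario_id=self.spec.id,
        )


def remaining_life_expectancy(
    model: ScenarioModel, sex: int, year: int, entry_age: int = 65
) -> LifeTableResult:
    """State-decomposed remaining life expectancy (see ScenarioModel.life_table)."""
    return model.life_table(sex, year, entry_age=entry_age)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


class TargetUnreachableError(ValueError):
    pass


def _le(params, spec, sex, year, **model_kw) -> LifeTableResult:
    return ScenarioModel(params, spec, **model_kw).life_table(sex, year)


def calibrate(
    params: LatentModelParams,
    spec: ScenarioSpec,
    sex: int,
    year: int = 2050,
    x_max: float = 0.5,
    xtol: float = 1e-7,
    **model_kw,
) -> tuple[ScenarioSpec, dict]:
    """Solve the scenario's annual rate(s) so LE at 65 in ``year`` hits target.

    Expansion/compression: scalar bisection-type root find on the annual rate.
    Dynamic: nested solve -- the outer rate targets LE while an inner rate on
    dying out of poor health holds expected poor-state years at their
    baseline value.  Returns the calibrated spec and an iteration report.
    """
    if spec.hypothesis == "baseline":
        raise ValueError("the baseline scenario is not calibrated")
    if sex not in spec.le_targets:
        raise ValueError(f"scenario '{spec.id}' has no LE target for sex {sex}")
    target = spec.le_targets[sex]
    trace: list[tuple[float, float]] = []

    if spec.hypothesis == "dynamic":
        base_lt = _le(params, ScenarioSpec("baseline", "baseline"), sex, year, **model_kw)
        poor_target = float(base_lt.by_state[POOR])

        def solve_poor_rate(x: float) -> float:
            def gap(x_pd: float) -> float:
                trial = replace(
                    spec, rates={**spec.rates, sex: x},
                    poor_death_rates={**spec.poor_death_rates, sex: x_pd},
                )
                return float(_le(params, trial, sex, year, **model_kw).by_state[POOR]) - poor_target

            if gap(0.0) >= 0.0:
                return 0.0
            hi = 1.0 - 1e-9
            if gap(hi) < 0.0:
                raise TargetUnreachableError(
                    f"scenario '{spec.id}': cannot hold poor-state years at "
                    f"{poor_target:.3f} for sex {sex} (rate {x:.4f})"
                )
            return float(brentq(gap, 0.0, hi, xtol=xtol))

        def le_gap(x: float) -> float:
            x_pd = solve_poor_rate(x)
            trial = replace(
                spec, rates={**spec.rates, sex: x},
                poor_death_rates={**spec.poor_death_rates, sex: x_pd},
            )
            le = _le(params, trial, sex, year, **model_kw).total
            trace.append((x, le))
            return le - target

    else:

        def le_gap(x: float) -> float:
            trial = replace(spec, rates={**spec.rates, sex: x})
            le = _le(params, trial, sex, year, **model_kw).total
            trace.append((x, le))
            return le - target

    g0 = le_gap(0.0)
    if g0 > 0.0:
        raise TargetUnreachableError(
            f"scenario '{spec.id}', sex {sex}: target LE {target} lies below the "
            f"unadjusted value {g0 + target:.3f}"
        )
    # expand the bracket upward until the target is straddled
    x_hi, g1 = 0.01, None
    while True:
        g1 = le_gap(x_hi)
        if g1 >= 0.0:
            break
        if x_hi >= x_max:
            raise TargetUnreachableError(
                f"scenario '{spec.id}', sex {sex}: target LE {target} outside the "
                f"achievable range [{g0 + target:.3f}, {g1 + target:.3f}] "
                f"for rates in [0, {x_max}]"
            )
        x_hi = min(2.0 * x_hi, x_max)
    x_star = 0.0 if g0 == 0.0 else float(brentq(le_gap, 0.0, x_hi, xtol=xtol))

    out = replace(spec, rates={**spec.rates, sex: x_star})
    if spec.hypothesis == "dynamic":
        out.poor_death_rates = {**spec.poor_death_rates, sex: solve_poor_rate(x_star)}
    achieved = _le(params, out, sex, year, **model_kw)
    report = {
        "scenario": spec.id,
        "sex": SEX_NAMES[sex],
        "target_le": target,
        "achieved_le": achieved.total,
        "rate": x_star,
        "poor_death_rate": out.poor_death_rates.get(sex),
        "n_evaluations": len(trace),
        "trace": trace,
    }
    return out, report


def calibrate_all(
    params: LatentModelParams,
    scenario_ids=None,
    sexes=(0, 1),
    year: int = 2050,
    **model_kw,
):
    """Calibrate every requested scenario for every sex.

    Returns ``(specs, reports)``: calibrated specs keyed by scenario id and a
    list of per-(scenario, sex) calibration reports (the baseline is marked
    not applicable).
    """
    catalog = scenario_catalog()
    scenario_ids = scenario_ids or list(catalog)
    specs: dict[str, ScenarioSpec] = {}
    reports = []
    for sid in scenario_ids:
        spec = catalog[sid]
        if spec.hypothesis == "baseline":
            specs[sid] = spec
            reports.append({"scenario": sid, "calibration": "not applicable"})
            continue
        for sex in sexes:
            spec, rep = calibrate(params, spec, sex, year=year, **model_kw)
            reports.append(rep)
        specs[sid] = spec
    return specs, reports
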