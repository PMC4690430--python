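"""Reporting perspectives: lifetime costs, aggregate expenditures, growth.

Three views of a calibrated scenario: (i) expected remaining lifetime cost
at 65 decomposed by the health state in which it accrues, per service;
(ii) population pyramids (via the cohort projection); (iii) aggregate annual
expenditure series 2010-2050 and their geometric-mean growth rates.  Costs
are undiscounted, in abstract cost units, accrue to the state occupied at
the start of each year, and the year of death carries a half-year credit --
the same conventions as the life table.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import expected_annual_cost
from .params import SERVICES, LatentModelParams
from .projection import AGES, EntrantSeries, PopulationState, PopulationTrajectory, project, pyramid
from .scenarios import SEX_NAMES, ScenarioModel, ScenarioSpec

__all__ = [
    "LifetimeCostResult",
    "ExpenditureSeries",
    "lifetime_costs",
    "aggregate_expenditures",
    "annual_growth_rate",
    "expected_cost_table",
    "report_bundle",
]


@dataclass
class LifetimeCostResult:
    """Expected remaining lifetime cost at entry age, by service and state."""

    by_state: dict[str, np.ndarray]  # service -> (L,) cost units
    sex: int
    entry_age: int
    year: int
    scenario_id: str
    stream: dict[str, np.ndarray] | None = None  # service -> per-year accruals

    def total(self, service: str) -> float:
        return float(self.by_state[service].sum())


@dataclass
class ExpenditureSeries:
    """Aggregate annual expenditure of one service under one scenario."""

    years: np.ndarray
    values: np.ndarray
    service: str
    scenario_id: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("expenditures must be non-negative")


def expected_cost_table(params: LatentModelParams, service: str) -> np.ndarray:
    """Expected annual cost over the projection grid: (n_ages, sex, state)."""
    L = params.n_living
    out = np.zeros((len(AGES), 2, L))
    for sex in (0, 1):
        for m in range(L):
            out[:, sex, m] = expected_annual_cost(params, m, sex, AGES, service)
    return out


def lifetime_costs(
    scenario_model: ScenarioModel,
    sex: int,
    year: int = 2050,
    entry_age: int = 65,
    services: tuple[str, ...] = SERVICES,
    return_stream: bool = False,
) -> LifetimeCostResult:
    """Expected remaining lifetime costs at 65 under the period convention.

    Sums projected occupancy x expected annual cost over the remaining
    lifetime, with the year-of-death half-credit, decomposed by the state in
    which the cost accrues.
    """
    params = scenario_model.params
    for s in services:
        if params.costs.get(s) is None:
            raise ValueError(f"no fitted cost model for service '{s}'")
    L = params.n_living
    occ = scenario_model.initial_profile(year, sex)
    by_state = {s: np.zeros(L) for s in services}
    n_years = scenario_model.age_cap - entry_age
    stream = {s: np.zeros(n_years) for s in services} if return_stream else None
    half = 0.5 if scenario_model.half_year_correction else 0.0
    ages_vec = np.arange(entry_age, scenario_model.age_cap)
    cost_by_age = {
        s: np.stack(
            [
                expected_annual_cost(params, m, sex, ages_vec, s,
                                     partner=scenario_model.partner,
                                     education=scenario_model.education)
                for m in range(L)
            ],
            axis=1,
        )
        for s in services
    }  # service -> (n_years, L)
    for k, age in enumerate(ages_vec):
        P = scenario_model.transition_matrix(sex, int(age), year)
        person_years = occ * (1.0 - half * P[:L, -1])
        for s in services:
            accrual = person_years * cost_by_age[s][k]
            by_state[s] += accrual
            if return_stream:
                stream[s][k] = accrual.sum()
        occ = occ @ P[:L, :L]
    return LifetimeCostResult(
        by_state=by_state, sex=sex, entry_age=entry_age, year=year,
        scenario_id=scenario_model.spec.id, stream=stream,
    )


def aggregate_expenditures(
    trajectory: PopulationTrajectory,
    scenario_model: ScenarioModel,
    service: str,
) -> ExpenditureSeries:
    """Annual aggregate expenditure: persons x expected annual cost per cell,
    with the half-year credit on cells dying during the year."""
    table = expected_cost_table(scenario_model.params, service)
    years, values = [], []
    for state in trajectory.states:
        v = float((state.counts * table).sum())
        if state.deaths_next is not None:
            v -= 0.5 * float((state.deaths_next * table).sum())
        years.append(state.year)
        values.append(v)
    return ExpenditureSeries(
        years=np.array(years), values=np.array(values), service=service,
        scenario_id=trajectory.scenario_id, provenance=dict(trajectory.provenance),
    )


def annual_growth_rate(series: ExpenditureSeries) -> float:
    """Geometric-mean annual growth in percent over the series' span."""
    start, end = series.values[0], series.values[-1]
    if start <= 0 or end <= 0:
        raise ValueError("growth rate requires positive first and last values")
    span = series.years[-1] - series.years[0]
    return float(((end / start) ** (1.0 / span) - 1.0) * 100.0)


def _model_hash(params: LatentModelParams) -> str:
    return hashlib.md5(
        json.dumps(params.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:12]


def report_bundle(
    params: LatentModelParams,
    specs: dict[str, ScenarioSpec],
    outdir,
    initial: PopulationState,
    entrants: EntrantSeries,
    year: int = 2050,
    services: tuple[str, ...] = SERVICES,
    seeds: dict | None = None,
) -> dict:
    """Write the three reporting perspectives for every calibrated scenario.

    Produces tidy CSV tables (life expectancy + lifetime costs by state;
    population pyramids for 2010 and the target year; expenditure series and
    growth rates) plus a JSON manifest binding every output to the scenario
    ids, a model hash and the seeds.  Uncalibrated scenarios are listed and
    skipped with a warning.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    skipped = []
    le_rows, pyr_rows, exp_rows, growth_rows = [], [], [], []
    for sid, spec in specs.items():
        if not all(spec.calibrated_for(sex) for sex in (0, 1)):
            warnings.warn(f"scenario '{sid}' is not calibrated; skipped in the report")
            skipped.append(sid)
            continue
        model = ScenarioModel(params, spec)
        for sex in (0, 1):
            lt = model.life_table(sex, year)
            lc = lifetime_costs(model, sex, year, services=services)
            row = {
                "scenario": sid, "sex": SEX_NAMES[sex], "year": year,
                "life_expectancy": lt.total,
            }
            for m in range(params.n_living):
                row[f"years_state_{m + 1}"] = lt.by_state[m]
            for s in services:
                row[f"cost_{s}_total"] = lc.total(s)
                for m in range(params.n_living):
                    row[f"cost_{s}_state_{m + 1}"] = lc.by_state[s][m]
            le_rows.append(row)
        traj = project(initial, entrants, model, end_year=year)
        for py in (initial.year, year):
            p = pyramid(traj, py)
            p.insert(0, "scenario", sid)
            p.insert(1, "year", py)
            pyr_rows.append(p)
        for s in services:
            series = aggregate_expenditures(traj, model, s)
            for yy, vv in zip(series.years, series.values):
                exp_rows.append({"scenario": sid, "service": s, "year": yy, "expenditure": vv})
            growth_rows.append(
                {"scenario": sid, "service": s,
                 "annual_growth_pct": annual_growth_rate(series)}
            )
    pd.DataFrame(le_rows).to_csv(outdir / "life_expectancy_lifetime_costs.csv", index=False)
    pd.concat(pyr_rows, ignore_index=True).to_csv(outdir / "pyramids.csv", index=False)
    pd.DataFrame(exp_rows).to_csv(outdir / "expenditure_series.csv", index=False)
    pd.DataFrame(growth_rows).to_csv(outdir / "growth_rates.csv", index=False)
    from . import __version__

    manifest = {
        "version": __version__,
        "scenarios": {
            sid: {
                "rates": {SEX_NAMES[k]: v for k, v in spec.rates.items()},
                "poor_death_rates": {SEX_NAMES[k]: v for k, v in spec.poor_death_rates.items()},
                "calibrated": sid not in skipped,
            }
            for sid, spec in specs.items()
        },
        "skipped": skipped,
        "model_hash": _model_hash(params),
        "seeds": seeds or {},
        "target_year": year,
        "files": [
            "life_expectancy_lifetime_costs.csv", "pyramids.csv",
            "expenditure_series.csv", "growth_rates.csv",
        ],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
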