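"""Deterministic cohort-component projection of the 65+ population by state.

The projected population is a counts array over age (65-109), sex and living
health state.  Each year, every cell is redistributed by the scenario-
adjusted transition matrix for its age/sex and the calendar year, ages
advance by one, survivors reaching the age cap are removed, and a new cohort
of 65-year-olds enters with the scenario's initial health profile.  The
projection is an expected-value (matrix) computation; a seeded individual-
level microsimulation of the same model is provided as a cross-check oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .scenarios import ScenarioModel, baseline_profile_at_65

__all__ = [
    "AGES",
    "PopulationState",
    "EntrantSeries",
    "PopulationTrajectory",
    "init_population",
    "default_population_inputs",
    "step_year",
    "project",
    "pyramid",
    "microsimulate",
]

#: Single-year ages tracked by the projection; the cap removes survivors
#: who would turn 110.
AGES = np.arange(65, 110)
N_AGES = len(AGES)


@dataclass
class PopulationState:
    """Population counts by age x sex x living state in one calendar year.

    ``deaths_next`` (same shape) holds deaths occurring during the step that
    starts this year, attributed to the origin cell; ``cap_removed_next``
    holds survivors removed at the age cap during that step.
    """

    year: int
    counts: np.ndarray  # (N_AGES, 2, L)
    deaths_next: np.ndarray | None = None
    cap_removed_next: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 3 or self.counts.shape[:2] != (N_AGES, 2):
            raise ValueError(f"counts must have shape ({N_AGES}, 2, n_living_states)")
        if (self.counts < 0).any():
            raise ValueError("population counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def total_deaths_next(self) -> float:
        d = 0.0 if self.deaths_next is None else float(self.deaths_next.sum())
        return d + self.cap_removed_next


@dataclass
class EntrantSeries:
    """New 65-year-olds per calendar year and sex."""

    start_year: int
    counts: np.ndarray  # (n_years, 2)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if (self.counts < 0).any():
            raise ValueError("entrant counts must be non-negative")

    def get(self, year: int, sex: int) -> float:
        i = year - self.start_year
        if not 0 <= i < len(self.counts):
            return 0.0
        return float(self.counts[i, sex])

    @classmethod
    def flat(cls, count: float = 10_000.0, start_year: int = 2011, end_year: int = 2050):
        n = end_year - start_year + 1
        return cls(start_year, np.full((n, 2), count))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"year": self.start_year + i, "sex": s, "count": self.counts[i, s]}
            for i in range(len(self.counts))
            for s in (0, 1)
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EntrantSeries":
        years = np.sort(df["year"].unique())
        counts = np.zeros((len(years), 2))
        for _, r in df.iterrows():
            counts[int(r["year"]) - years[0], int(r["sex"])] = r["count"]
        return cls(int(years[0]), counts)


@dataclass
class PopulationTrajectory:
    """Consecutive population states 2010-2050 plus provenance."""

    states: list[PopulationState]
    scenario_id: str
    provenance: dict = field(default_factory=dict)

    @property
    def years(self) -> list[int]:
        return [s.year for s in self.states]

    def get(self, year: int) -> PopulationState:
        for s in self.states:
            if s.year == year:
                return s
        raise KeyError(f"year {year} not in trajectory ({self.years[0]}-{self.years[-1]})")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.states:
            L = s.counts.shape[2]
            for ai, age in enumerate(AGES):
                for sex in (0, 1):
                    for m in range(L):
                        rows.append((s.year, sex, age, m, s.counts[ai, sex, m]))
        return pd.DataFrame(rows, columns=["year", "sex", "age", "state", "persons"])

    def write_csv(self, path) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        sidecar = path.with_suffix(".provenance.json")
        sidecar.write_text(json.dumps({"scenario": self.scenario_id, **self.provenance}, indent=1))


def init_population(counts_by_age_sex: np.ndarray, state_shares: np.ndarray,
                    year: int = 2010) -> PopulationState:
    """Allocate an age/sex stock to living states by the given shares.

    ``counts_by_age_sex`` is (N_AGES, 2); ``state_shares`` is (N_AGES, 2, L)
    and must sum to 1 over states in every cell with population.
    """
    counts_by_age_sex = np.asarray(counts_by_age_sex, dtype=float)
    state_shares = np.asarray(state_shares, dtype=float)
    occupied = counts_by_age_sex > 0
    sums = state_shares.sum(axis=2)
    if np.any(np.abs(sums[occupied] - 1.0) > 1e-9):
        raise ValueError("state shares must sum to 1 in every populated age/sex cell")
    return PopulationState(year=year, counts=counts_by_age_sex[:, :, None] * state_shares)


def default_population_inputs(params, cohort_size: float = 10_000.0,
                              max_stock_age: int = 95, entrants_per_year: float | None = None):
    """Synthetic default demographic inputs.

    The 2010 stock is the stationary age profile of the baseline model --
    ``cohort_size`` persons entering at 65 per sex per year, aged forward by
    baseline survival -- truncated at ``max_stock_age`` (the emulated base
    population covers ages 65-95).  Entrant cohorts are flat at
    ``entrants_per_year`` (default: ``cohort_size``).  Age/sex state shares
    come from ageing the 65-year-old baseline health profile.
    """
    from .scenarios import ScenarioSpec

    L = params.n_living
    base = ScenarioModel(params, ScenarioSpec("baseline", "baseline"))
    shares = np.zeros((N_AGES, 2, L))
    counts = np.zeros((N_AGES, 2))
    for sex in (0, 1):
        occ = baseline_profile_at_65(params, sex) * cohort_size
        for ai, age in enumerate(AGES):
            shares[ai, sex] = occ / occ.sum()
            counts[ai, sex] = occ.sum() if age <= max_stock_age else 0.0
            P = base.transition_matrix(sex, age, 2010)
            occ = occ @ P[:L, :L]
    initial = init_population(counts, shares, year=2010)
    entrants = EntrantSeries.flat(
        cohort_size if entrants_per_year is None else entrants_per_year, 2011, 2050
    )
    return initial, entrants


def step_year(state: PopulationState, scenario_model: ScenarioModel,
              entrants: EntrantSeries | None = None) -> PopulationState:
    """Advance the population one year.

    Each age/sex/state cell is redistributed by the scenario transition
    matrix of the current calendar year; ages advance; deaths are recorded on
    the origin cells of ``state``; survivors leaving the top age are removed;
    entrants (if given) are added at 65 with the scenario's initial profile.
    """
    L = state.counts.shape[2]
    year = state.year
    new_counts = np.zeros_like(state.counts)
    deaths = np.zeros_like(state.counts)
    cap_removed = 0.0
    for sex in (0, 1):
        for ai, age in enumerate(AGES):
            occ = state.counts[ai, sex]
            if occ.sum() == 0:
                continue
            P = scenario_model.transition_matrix(sex, age, year)
            deaths[ai, sex] = occ * P[:L, -1]
            survivors = occ @ P[:L, :L]
            if ai + 1 < N_AGES:
                new_counts[ai + 1, sex] += survivors
            else:
                cap_removed += survivors.sum()
    state.deaths_next = deaths
    state.cap_removed_next = cap_removed
    if entrants is not None:
        for sex in (0, 1):
            n = entrants.get(year + 1, sex)
            if n > 0:
                new_counts[0, sex] += n * scenario_model.initial_profile(year + 1, sex)
    return PopulationState(year=year + 1, counts=new_counts)


def project(initial: PopulationState, entrants: EntrantSeries,
            scenario_model: ScenarioModel, end_year: int = 2050) -> PopulationTrajectory:
    """Run the deterministic projection from the initial year to ``end_year``.

    Every year's state carries the deaths of the following step (the final
    year's deaths come from one extra step whose result is discarded), so
    downstream expenditure accounting can apply the half-year death credit.
    """
    spec = scenario_model.spec
    for sex in (0, 1):
        if spec.hypothesis != "baseline" and not spec.calibrated_for(sex):
            raise ValueError(f"scenario '{spec.id}' must be calibrated before projecting")
    states = [initial]
    while states[-1].year < end_year:
        states.append(step_year(states[-1], scenario_model, entrants))
    step_year(states[-1], scenario_model)  # fill final-year deaths
    return PopulationTrajectory(
        states=states,
        scenario_id=spec.id,
        provenance={"base_year": scenario_model.base_year,
                    "rates": {str(k): v for k, v in spec.rates.items()},
                    "poor_death_rates": {str(k): v for k, v in spec.poor_death_rates.items()}},
    )


def pyramid(trajectory: PopulationTrajectory, year: int, bin_width: int = 5) -> pd.DataFrame:
    """Persons per age bin x sex x state for one projected year."""
    s = trajectory.get(year)
    L = s.counts.shape[2]
    edges = np.arange(AGES[0], AGES[-1] + bin_width + 1, bin_width)
    rows = []
    for lo in edges[:-1]:
        hi = min(lo + bin_width - 1, AGES[-1])
        sel = (AGES >= lo) & (AGES <= hi)
        if not sel.any():
            continue
        for sex in (0, 1):
            for m in range(L):
                rows.append(
                    {"age_group": f"{lo}-{hi}", "sex": sex, "state": m,
                     "persons": float(s.counts[sel, sex, m].sum())}
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# microsimulation cross-check
# ---------------------------------------------------------------------------


@dataclass
class MicrosimResult:
    """Scaled counts from an individual-level simulation of the projection.

    ``counts[t]`` mirrors the deterministic trajectory; ``batch_counts`` has
    an extra leading batch axis whose spread yields Monte-Carlo standard
    errors (each batch is an equal-probability subsample scaled to the full
    population).  ``expenditure``/``batch_expenditure`` accumulate expected
    annual cost per realised person-year with the half-year death credit,
    per service.
    """

    years: list[int]
    counts: np.ndarray          # (T, N_AGES, 2, L)
    batch_counts: np.ndarray    # (B, T, N_AGES, 2, L)
    expenditure: dict[str, np.ndarray]        # service -> (T,)
    batch_expenditure: dict[str, np.ndarray]  # service -> (B, T)
    n_individuals: int

    def se_counts(self) -> np.ndarray:
        B = self.batch_counts.shape[0]
        return self.batch_counts.std(axis=0, ddof=1) / np.sqrt(B)

    def se_expenditure(self, service: str) -> np.ndarray:
        B = self.batch_expenditure[service].shape[0]
        return self.batch_expenditure[service].std(axis=0, ddof=1) / np.sqrt(B)


def microsimulate(
    scenario_model: ScenarioModel,
    initial: PopulationState,
    entrants: EntrantSeries,
    n: int = 50_000,
    seed: int = 0,
    end_year: int = 2050,
    n_batches: int = 10,
    services: tuple[str, ...] = (),
) -> MicrosimResult:
    """Stochastic individual-level simulation of the same projection model.

    ``n`` individuals represent the initial stock (each with weight
    total/n); entrant cohorts get the same weight.  Expenditures accrue the
    *expected* annual cost of each realised (state, age, sex) cell so that
    differences from the deterministic projection reflect occupancy
    randomness only.
    """
    from .outcomes import expected_cost_table

    rng = np.random.default_rng(seed)
    params = scenario_model.params
    L = params.n_living
    total0 = initial.total
    w = total0 / n

    # sample initial individuals from the stock distribution
    p_cells = (initial.counts / total0).reshape(-1)
    cells = rng.choice(p_cells.size, size=n, p=p_cells)
    age_i, sex_i, state_i = np.unravel_index(cells, initial.counts.shape)
    batch = np.arange(n) % n_batches

    years = list(range(initial.year, end_year + 1))
    T = len(years)
    counts = np.zeros((T, N_AGES, 2, L))
    batch_counts = np.zeros((n_batches, T, N_AGES, 2, L))
    exp_tot = {s: np.zeros(T) for s in services}
    exp_batch = {s: np.zeros((n_batches, T)) for s in services}
    cost_tables = {s: expected_cost_table(params, s) for s in services}

    n_total = n
    for t, year in enumerate(years):
        # occupancy bookkeeping
        np.add.at(counts[t], (age_i, sex_i, state_i), w)
        np.add.at(batch_counts, (batch, t, age_i, sex_i, state_i), w * n_batches)

        # transition matrices for this year, by age x sex
        P_all = np.zeros((N_AGES, 2, L, L + 1))
        for sex in (0, 1):
            for ai in range(N_AGES):
                P = scenario_model.transition_matrix(sex, AGES[ai], year)
                P_all[ai, sex] = P[:L]
        rows = P_all[age_i, sex_i, state_i]  # (alive, L+1)
        u = rng.random(len(age_i))
        nxt = (u[:, None] > np.cumsum(rows, axis=1)).sum(axis=1)
        died = nxt == L
        at_cap = age_i == N_AGES - 1

        for s in services:
            # full-year cost for survivors, half for those dying this step
            c = cost_tables[s][age_i, sex_i, state_i]
            credit = np.where(died, 0.5, 1.0) * c * w
            np.add.at(exp_tot[s], np.full(len(c), t), credit)
            np.add.at(exp_batch[s], (batch, np.full(len(c), t)), credit * n_batches)

        if year == end_year:
            break
        keep = ~died & ~at_cap
        age_i, sex_i, state_i, batch = age_i[keep] + 1, sex_i[keep], nxt[keep], batch[keep]

        # entrants at 65
        add_age, add_sex, add_state, add_batch = [], [], [], []
        for sex in (0, 1):
            n_e = int(round(entrants.get(year + 1, sex) / w))
            if n_e <= 0:
                continue
            profile = scenario_model.initial_profile(year + 1, sex)
            st = (rng.random(n_e)[:, None] > np.cumsum(profile)).sum(axis=1)
            add_age.append(np.zeros(n_e, dtype=int))
            add_sex.append(np.full(n_e, sex))
            add_state.append(st)
            add_batch.append((np.arange(n_total, n_total + n_e)) % n_batches)
            n_total += n_e
        if add_age:
            age_i = np.concatenate([age_i, *add_age])
            sex_i = np.concatenate([sex_i, *add_sex])
            state_i = np.concatenate([state_i, *add_state])
            batch = np.concatenate([batch, *add_batch])

    return MicrosimResult(
        years=years, counts=counts, batch_counts=batch_counts,
        expenditure=exp_tot, batch_expenditure=exp_batch, n_individuals=n_total,
    )
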