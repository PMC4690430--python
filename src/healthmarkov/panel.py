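"""Individual-year panel data: containers, validation, file round-trip.

A panel holds one row per individual per calendar year from entry until death
(or the end of the observation window).  Health indicators are observed only
in survey years; each cost service is observed only inside its registry
window; the year of death carries the death observation itself and no
indicator or cost values.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import SERVICES, CovariateSpec, IndicatorScheme, default_indicator_scheme

__all__ = ["ObservationSchedule", "PanelDataset", "PanelArrays", "apply_observation_schedule"]

VITAL_ALIVE = "alive"
VITAL_DIED = "died"

_INDICATOR_COLS = [f"y{j + 1}" for j in range(7)]
_COST_COLS = [f"cost_{s}" for s in SERVICES]
_COLUMNS = (
    ["id", "year", "sex", "partner", "age", "education"]
    + _INDICATOR_COLS
    + _COST_COLS
    + ["vital_status"]
)


@dataclass(frozen=True)
class ObservationSchedule:
    """Which years carry which observations.

    ``survey_years`` are the calendar years with indicator interviews;
    ``registry_windows`` maps each service to its (first, last) observed year.
    """

    start_year: int
    end_year: int
    survey_years: tuple[int, ...]
    registry_windows: dict[str, tuple[int, int]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "start_year": self.start_year,
            "end_year": self.end_year,
            "survey_years": list(self.survey_years),
            "registry_windows": {s: list(w) for s, w in self.registry_windows.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ObservationSchedule":
        return cls(
            start_year=d["start_year"],
            end_year=d["end_year"],
            survey_years=tuple(d["survey_years"]),
            registry_windows={s: tuple(w) for s, w in d["registry_windows"].items()},
        )


class PanelDataset:
    """An individual-year panel plus its observation-schedule metadata.

    The underlying frame has columns id, year, sex, partner, age, education,
    y1..y7 (nullable integer categories), cost_hospital / cost_homecare /
    cost_ltc (float, NaN = unobserved) and vital_status ('alive' or 'died').
    """

    def __init__(
        self,
        df: pd.DataFrame,
        schedule: ObservationSchedule,
        scheme: IndicatorScheme | None = None,
        validate: bool = True,
    ) -> None:
        self.scheme = scheme or default_indicator_scheme()
        if self.scheme.n_indicators != 7:
            raise ValueError("panel files carry exactly 7 indicator columns")
        df = df.copy()
        for c in _INDICATOR_COLS:
            df[c] = df[c].astype("Int64")
        for c in _COST_COLS:
            df[c] = df[c].astype(float)
        self.df = df[_COLUMNS].reset_index(drop=True)
        self.schedule = schedule
        if validate:
            self.validate()

    # -- invariants -------------------------------------------------------

    def validate(self) -> None:
        df = self.df
        dup = df.duplicated(subset=["id", "year"])
        if dup.any():
            i = int(np.flatnonzero(dup.to_numpy())[0])
            raise ValueError(
                f"duplicated individual-year key at row {i} "
                f"(id={df.at[i, 'id']}, year={df.at[i, 'year']})"
            )
        bad = ~df["vital_status"].isin([VITAL_ALIVE, VITAL_DIED])
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"invalid vital_status at row {i}, column 'vital_status'")
        for c in _COST_COLS:
            neg = df[c] < 0
            if neg.any():
                i = int(np.flatnonzero(neg.to_numpy())[0])
                raise ValueError(f"negative cost at row {i}, column '{c}'")
        for j, c in enumerate(_INDICATOR_COLS):
            k = self.scheme.n_categories[j]
            vals = df[c]
            bad = vals.notna() & ((vals < 0) | (vals >= k))
            if bad.any():
                i = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValueError(
                    f"indicator category out of range at row {i}, column '{c}'"
                )
        # per-individual structure: consecutive years, death terminal
        for ind, g in df.groupby("id", sort=False):
            years = g["year"].to_numpy()
            if len(years) > 1 and not np.all(np.diff(years) == 1):
                raise ValueError(f"non-consecutive years for individual {ind}")
            died = (g["vital_status"] == VITAL_DIED).to_numpy()
            if died[:-1].any():
                raise ValueError(f"records exist after death for individual {ind}")
            death_rows = g[g["vital_status"] == VITAL_DIED]
            if not death_rows.empty:
                r = death_rows.iloc[0]
                if r[_INDICATOR_COLS].notna().any() or r[_COST_COLS].notna().any():
                    raise ValueError(
                        f"death-year record for individual {ind} must carry no "
                        "indicator or cost values"
                    )

    # -- convenience ------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.df["id"].nunique()

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PanelDataset):
            return NotImplemented
        return self.schedule == other.schedule and self.df.equals(other.df)

    def individual(self, ind) -> pd.DataFrame:
        return self.df[self.df["id"] == ind]

    # -- file round-trip --------------------------------------------------

    def write_csv(self, path) -> None:
        """Plain-text panel file: '#schedule' JSON header line + CSV body."""
        buf = io.StringIO()
        buf.write("#schedule " + json.dumps(self.schedule.to_dict(), sort_keys=True) + "\n")
        out = self.df.copy()
        # fixed float formatting keeps write->read->write byte-stable
        for c in _COST_COLS:
            out[c] = out[c].map(lambda v: "" if pd.isna(v) else f"{v:.2f}")
        for c in _INDICATOR_COLS:
            out[c] = out[c].map(lambda v: "" if pd.isna(v) else str(int(v)))
        out.to_csv(buf, index=False)
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(buf.getvalue())

    @classmethod
    def read_csv(cls, path, scheme: IndicatorScheme | None = None) -> "PanelDataset":
        with open(path, encoding="utf-8") as fh:
            first = fh.readline()
            if not first.startswith("#schedule "):
                raise ValueError(f"{path}: missing '#schedule' header line (row 0)")
            schedule = ObservationSchedule.from_dict(json.loads(first[len("#schedule "):]))
            body = fh.read()
        df = pd.read_csv(io.StringIO(body))
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing column(s) {missing} in header row")
        return cls(df, schedule, scheme=scheme)

    # -- fitting arrays ---------------------------------------------------

    def to_arrays(self, covariates: CovariateSpec) -> "PanelArrays":
        return PanelArrays.from_panel(self, covariates)


def apply_observation_schedule(
    panel: PanelDataset,
    survey_interval: int,
    registry_windows: dict[str, tuple[int, int]],
) -> PanelDataset:
    """Mask emissions to the observation schedule.

    Indicators are kept only in survey years (every ``survey_interval``-th
    year from the panel start); each service's costs are kept only inside its
    registry window.  Death-year records are untouched (they carry no
    emissions).  Latent states are never part of a panel.
    """
    sched = panel.schedule
    y0, y1 = sched.start_year, sched.end_year
    for s, (a, b) in registry_windows.items():
        if a > b or a < y0 or b > y1:
            raise ValueError(f"registry window {a}-{b} for '{s}' outside panel years {y0}-{y1}")
    survey_years = tuple(range(y0, y1 + 1, survey_interval))
    df = panel.df.copy()
    alive = df["vital_status"] == VITAL_ALIVE
    off_survey = ~df["year"].isin(survey_years) & alive
    df.loc[off_survey, _INDICATOR_COLS] = pd.NA
    for s in SERVICES:
        a, b = registry_windows.get(s, (y0, y1))
        outside = (~df["year"].between(a, b)) & alive
        df.loc[outside, f"cost_{s}"] = np.nan
    new_sched = ObservationSchedule(
        start_year=y0,
        end_year=y1,
        survey_years=survey_years,
        registry_windows={s: registry_windows.get(s, (y0, y1)) for s in SERVICES},
    )
    return PanelDataset(df, new_sched, scheme=panel.scheme)


@dataclass
class PanelArrays:
    """Padded per-individual arrays used by the likelihood machinery.

    Shapes use N individuals and Tmax panel years.  ``valid[i, t]`` marks real
    records; ``dead[i, t]`` marks the death-year record.  Indicator categories
    use -1 for missing, costs use NaN for unobserved.
    """

    ids: np.ndarray          # (N,) object
    valid: np.ndarray        # (N, Tmax) bool
    dead: np.ndarray         # (N, Tmax) bool
    year: np.ndarray         # (N, Tmax) int
    y: np.ndarray            # (N, Tmax, J) int, -1 missing
    costs: np.ndarray        # (N, Tmax, 3) float, NaN unobserved
    x_trans: np.ndarray      # (N, Tmax, p_t)
    x_cost: np.ndarray       # (N, Tmax, p_c)
    x_init: np.ndarray       # (N, p_0)
    covariates: CovariateSpec
    scheme: IndicatorScheme

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def t_max(self) -> int:
        return self.valid.shape[1]

    @classmethod
    def from_panel(cls, panel: PanelDataset, covariates: CovariateSpec) -> "PanelArrays":
        df = panel.df.sort_values(["id", "year"], kind="mergesort")
        groups = list(df.groupby("id", sort=False))
        n = len(groups)
        if n == 0:
            raise ValueError("panel is empty")
        tmax = max(len(g) for _, g in groups)
        J = panel.scheme.n_indicators
        ids = np.empty(n, dtype=object)
        valid = np.zeros((n, tmax), dtype=bool)
        dead = np.zeros((n, tmax), dtype=bool)
        year = np.zeros((n, tmax), dtype=int)
        y = np.full((n, tmax, J), -1, dtype=int)
        costs = np.full((n, tmax, len(SERVICES)), np.nan)
        sex = np.zeros((n, tmax))
        partner = np.zeros((n, tmax))
        age = np.full((n, tmax), covariates.age_center)
        edu = np.zeros((n, tmax), dtype=int)
        x_init = np.zeros((n, covariates.n_init))
        for i, (ind, g) in enumerate(groups):
            T = len(g)
            ids[i] = ind
            valid[i, :T] = True
            dead[i, :T] = (g["vital_status"] == VITAL_DIED).to_numpy()
            year[i, :T] = g["year"].to_numpy()
            ymat = g[_INDICATOR_COLS].to_numpy(dtype=float, na_value=np.nan)
            obs = ~np.isnan(ymat)
            y[i, :T][obs] = ymat[obs].astype(int)
            costs[i, :T] = g[_COST_COLS].to_numpy(dtype=float, na_value=np.nan)
            sex[i, :T] = g["sex"].to_numpy()
            partner[i, :T] = g["partner"].to_numpy()
            age[i, :T] = g["age"].to_numpy()
            edu[i, :T] = g["education"].to_numpy()
            r0 = g.iloc[0]
            x_init[i] = covariates.init_vector(float(r0["age"]), float(r0["sex"]))
        x_trans = covariates.trans_vector(sex, partner, age, edu)
        x_cost = covariates.cost_vector(sex, partner, age, edu, year)
        return cls(
            ids=ids, valid=valid, dead=dead, year=year, y=y, costs=costs,
            x_trans=x_trans, x_cost=x_cost, x_init=x_init,
            covariates=covariates, scheme=panel.scheme,
        )
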