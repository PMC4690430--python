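"""Static report figures: state profiles, cost curves, pyramids, series.

All functions take an optional matplotlib Axes and return the Axes, so they
compose into report layouts; saving is left to the caller.
"""

from __future__ import annotations

import numpy as np

from .model import STATE_NAMES, expected_annual_cost
from .outcomes import ExpenditureSeries
from .projection import PopulationTrajectory, pyramid

__all__ = [
    "plot_state_profiles",
    "plot_cost_curves",
    "plot_pyramid",
    "plot_expenditure_series",
]

_STATE_COLORS = {"good": "#2a9d8f", "moderate": "#e9c46a", "poor": "#e76f51"}


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_state_profiles(profiles, ax=None):
    """Standardised expected indicator outcomes per state (0 best, 1 worst)."""
    ax = _ax(ax)
    x = np.arange(profiles.shape[1])
    for state, row in profiles.iterrows():
        ax.plot(x, row.to_numpy(), marker="o", label=state,
                color=_STATE_COLORS.get(state))
    ax.set_xticks(x, profiles.columns, rotation=45, ha="right")
    ax.set_ylabel("standardised expected outcome")
    ax.set_ylim(0, 1)
    ax.legend(title="latent state")
    return ax


def plot_cost_curves(params, service: str, sex: int = 0, ages=np.arange(65, 100), ax=None):
    """Expected annual cost by age per latent state, baseline covariates."""
    ax = _ax(ax)
    for m, name in enumerate(STATE_NAMES[: params.n_living]):
        ax.plot(ages, expected_annual_cost(params, m, sex, np.asarray(ages), service),
                label=name, color=_STATE_COLORS.get(name))
    ax.set_xlabel("age")
    ax.set_ylabel(f"expected annual {service} cost")
    ax.legend(title="latent state")
    return ax


def plot_pyramid(trajectory: PopulationTrajectory, year: int, ax=None, bin_width: int = 5):
    """Stacked population pyramid by health state (women left, men right)."""
    ax = _ax(ax)
    table = pyramid(trajectory, year, bin_width=bin_width)
    groups = table["age_group"].unique()
    y = np.arange(len(groups))
    for sex, sign in ((1, -1), (0, 1)):
        left = np.zeros(len(groups))
        for m, name in enumerate(STATE_NAMES):
            vals = np.array(
                [
                    table[(table.age_group == g) & (table.sex == sex) & (table.state == m)][
                        "persons"
                    ].sum()
                    for g in groups
                ]
            )
            ax.barh(y, sign * vals, left=sign * left, color=_STATE_COLORS[name],
                    label=name if sex == 0 else None)
            left += vals
    ax.set_yticks(y, groups)
    ax.set_xlabel("persons (women left, men right)")
    ax.set_title(f"health composition, {year}")
    ax.legend(title="latent state")
    return ax


def plot_expenditure_series(series_list: list[ExpenditureSeries], ax=None):
    """Aggregate expenditure 2010-2050, one line per scenario."""
    ax = _ax(ax)
    for ser in series_list:
        ax.plot(ser.years, ser.values, label=ser.scenario_id)
    ax.set_xlabel("calendar year")
    ax.set_ylabel(f"aggregate {series_list[0].service} expenditure")
    ax.legend(title="scenario", fontsize="small")
    return ax
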