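"""Parameter containers for the latent Markov health model.

The model has ``M`` latent states: ``M - 1`` living health states (ordered
good -> poor after labelling) plus death as an absorbing state.  Living-state
dynamics are driven by multinomial logits; emissions are per-indicator
multinomial logits (intercept-only) and per-service two-part cost models
(use logit + Gamma GLM with log link).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "SERVICES",
    "IndicatorScheme",
    "CovariateSpec",
    "TwoPartParams",
    "LatentModelParams",
    "default_indicator_scheme",
]

#: Service types, in the order used throughout the package.
SERVICES = ("hospital", "homecare", "ltc")

PARAMS_SCHEMA_VERSION = 1


def _softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - np.max(logits, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


@dataclass(frozen=True)
class IndicatorScheme:
    """Names and category counts of the categorical health indicators.

    Categories are coded ``0 .. K-1`` with 0 the best outcome and ``K-1``
    the worst.
    """

    names: tuple[str, ...]
    n_categories: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.n_categories):
            raise ValueError("names and n_categories must have equal length")
        if any(k < 2 for k in self.n_categories):
            raise ValueError("every indicator needs at least 2 categories")

    @property
    def n_indicators(self) -> int:
        return len(self.names)


def default_indicator_scheme() -> IndicatorScheme:
    """Seven indicators of physical and mental health in older adults.

    Self-perceived health (5 categories), self-reported mobility score (4),
    a timed performance test categorised into 3 levels, the Global Activity
    Limitation Indicator (3), chronic-disease count categorised 0/1/2+ (3),
    depressive symptoms above/below the CES-D cut-off (2) and cognitive
    impairment by MMSE cut-off (2).
    """
    return IndicatorScheme(
        names=(
            "self_perceived_health",
            "mobility",
            "performance",
            "gali",
            "chronic_diseases",
            "depression",
            "cognition",
        ),
        n_categories=(5, 4, 3, 3, 3, 2, 2),
    )


@dataclass(frozen=True)
class CovariateSpec:
    """Design-vector builders shared by transition and cost models.

    Age enters linearly per decade, centred at 75.  Education is a 3-level
    ordinal covariate entered as two dummies (reference: low).  Cost models
    additionally carry calendar-year dummies (reference: first level).
    """

    age_center: float = 75.0
    age_scale: float = 10.0
    year_levels: tuple[int, ...] = ()

    TRANS_NAMES = ("const", "female", "partner", "age_c", "edu_mid", "edu_high")
    INIT_NAMES = ("const", "age_c", "female")

    @property
    def n_trans(self) -> int:
        return len(self.TRANS_NAMES)

    @property
    def n_cost(self) -> int:
        return self.n_trans + max(len(self.year_levels) - 1, 0)

    @property
    def n_init(self) -> int:
        return len(self.INIT_NAMES)

    @property
    def cost_names(self) -> tuple[str, ...]:
        return self.TRANS_NAMES + tuple(f"year_{y}" for y in self.year_levels[1:])

    def age_c(self, age) -> np.ndarray:
        return (np.asarray(age, dtype=float) - self.age_center) / self.age_scale

    def trans_vector(self, sex, partner, age, education) -> np.ndarray:
        """Stack [1, female, partner, age_c, edu_mid, edu_high] along the last axis."""
        sex = np.asarray(sex, dtype=float)
        partner = np.asarray(partner, dtype=float)
        education = np.asarray(education)
        parts = [
            np.ones_like(sex),
            sex,
            partner,
            self.age_c(age) * np.ones_like(sex),
            (education == 1).astype(float),
            (education == 2).astype(float),
        ]
        return np.stack(np.broadcast_arrays(*parts), axis=-1)

    def cost_vector(self, sex, partner, age, education, year=None) -> np.ndarray:
        base = self.trans_vector(sex, partner, age, education)
        n_dum = max(len(self.year_levels) - 1, 0)
        if n_dum == 0:
            return base
        shape = base.shape[:-1]
        dums = np.zeros(shape + (n_dum,))
        if year is not None:
            year = np.broadcast_to(np.asarray(year), shape)
            for i, level in enumerate(self.year_levels[1:]):
                dums[..., i] = (year == level).astype(float)
        return np.concatenate([base, dums], axis=-1)

    def init_vector(self, age, sex) -> np.ndarray:
        sex = np.asarray(sex, dtype=float)
        parts = [np.ones_like(sex), self.age_c(age) * np.ones_like(sex), sex]
        return np.stack(np.broadcast_arrays(*parts), axis=-1)


@dataclass
class TwoPartParams:
    """Two-part cost model for one service: P(use) logit + Gamma log-link mean.

    ``use_coef`` and ``mean_coef`` have one row per living state; ``shape`` is
    the Gamma shape parameter, shared across states.  ``year_levels`` lists the
    calendar years behind the design's year dummies (first = reference); if
    None, the owning :class:`CovariateSpec`'s levels apply.
    """

    use_coef: np.ndarray
    mean_coef: np.ndarray
    shape: float
    year_levels: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        self.use_coef = np.asarray(self.use_coef, dtype=float)
        self.mean_coef = np.asarray(self.mean_coef, dtype=float)
        if self.use_coef.shape != self.mean_coef.shape:
            raise ValueError("use_coef and mean_coef must have the same shape")
        if not self.shape > 0:
            raise ValueError("Gamma shape must be positive")


@dataclass
class LatentModelParams:
    """Complete parameter set of the latent Markov health model.

    Attributes
    ----------
    n_states : int
        Number of latent states including death (death is the last state).
    init_coef : ndarray, (L, 3)
        Initial-state multinomial logit over living states on
        [1, age_c, female]; row 0 is the reference (zeros).
    trans_coef : ndarray, (L, M, n_trans)
        Per living origin state, destination logits over all M states; the
        origin's own row is the reference (zeros).  The death origin is
        implicitly absorbing.
    ind_logits : list of ndarray, each (L, K_j)
        Per-indicator multinomial logit intercepts (no covariates); category
        0 is the reference.
    costs : dict service -> TwoPartParams or None
    """

    n_states: int
    scheme: IndicatorScheme
    covariates: CovariateSpec
    init_coef: np.ndarray
    trans_coef: np.ndarray
    ind_logits: list[np.ndarray]
    costs: dict[str, TwoPartParams | None] = field(
        default_factory=lambda: {s: None for s in SERVICES}
    )

    def __post_init__(self) -> None:
        L = self.n_living
        self.init_coef = np.asarray(self.init_coef, dtype=float)
        self.trans_coef = np.asarray(self.trans_coef, dtype=float)
        self.ind_logits = [np.asarray(a, dtype=float) for a in self.ind_logits]
        if self.n_states < 2:
            raise ValueError("need at least one living state plus death")
        if self.init_coef.shape != (L, self.covariates.n_init):
            raise ValueError("init_coef has wrong shape")
        if self.trans_coef.shape != (L, self.n_states, self.covariates.n_trans):
            raise ValueError("trans_coef has wrong shape")
        if len(self.ind_logits) != self.scheme.n_indicators:
            raise ValueError("one logit block per indicator required")
        for a, k in zip(self.ind_logits, self.scheme.n_categories):
            if a.shape != (L, k):
                raise ValueError("indicator logit block has wrong shape")

    # -- basic structure -------------------------------------------------

    @property
    def n_living(self) -> int:
        return self.n_states - 1

    @property
    def death_state(self) -> int:
        return self.n_states - 1

    def copy(self) -> "LatentModelParams":
        return replace(
            self,
            init_coef=self.init_coef.copy(),
            trans_coef=self.trans_coef.copy(),
            ind_logits=[a.copy() for a in self.ind_logits],
            costs={
                s: (
                    None
                    if tp is None
                    else TwoPartParams(
                        tp.use_coef.copy(), tp.mean_coef.copy(), tp.shape, tp.year_levels
                    )
                )
                for s, tp in self.costs.items()
            },
        )

    # -- probability evaluations -----------------------------------------

    def initial_probs(self, x_init: np.ndarray) -> np.ndarray:
        """P(initial living state | age, sex); x_init (..., 3) -> (..., L)."""
        logits = np.einsum("...p,mp->...m", np.asarray(x_init, float), self.init_coef)
        return _softmax(logits)

    def transition_matrix(self, x_trans: np.ndarray) -> np.ndarray:
        """Full M x M annual transition matrix at covariates x_trans (..., p).

        Rows are origins; the death row is the absorbing unit vector.
        """
        x = np.asarray(x_trans, dtype=float)
        logits = np.einsum("...p,lmp->...lm", x, self.trans_coef)
        living = _softmax(logits, axis=-1)  # (..., L, M)
        out = np.zeros(x.shape[:-1] + (self.n_states, self.n_states))
        out[..., : self.n_living, :] = living
        out[..., self.death_state, self.death_state] = 1.0
        return out

    def transition_row(self, origin: int, x_trans: np.ndarray) -> np.ndarray:
        """One origin's transition probability row (softmax over destinations)."""
        if origin == self.death_state:
            row = np.zeros(self.n_states)
            row[self.death_state] = 1.0
            return row
        logits = np.asarray(x_trans, float) @ self.trans_coef[origin].T
        return _softmax(logits)

    def indicator_probs(self, indicator: int) -> np.ndarray:
        """P(category | living state) for one indicator, shape (L, K_j)."""
        return _softmax(self.ind_logits[indicator], axis=-1)

    # -- persistence ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema_version": PARAMS_SCHEMA_VERSION,
            "n_states": self.n_states,
            "scheme": {
                "names": list(self.scheme.names),
                "n_categories": list(self.scheme.n_categories),
            },
            "covariates": {
                "age_center": self.covariates.age_center,
                "age_scale": self.covariates.age_scale,
                "year_levels": list(self.covariates.year_levels),
            },
            "init_coef": self.init_coef.tolist(),
            "trans_coef": self.trans_coef.tolist(),
            "ind_logits": [a.tolist() for a in self.ind_logits],
            "costs": {
                s: (
                    None
                    if tp is None
                    else {
                        "use_coef": tp.use_coef.tolist(),
                        "mean_coef": tp.mean_coef.tolist(),
                        "shape": tp.shape,
                        "year_levels": None
                        if tp.year_levels is None
                        else list(tp.year_levels),
                    }
                )
                for s, tp in self.costs.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LatentModelParams":
        scheme = IndicatorScheme(
            names=tuple(d["scheme"]["names"]),
            n_categories=tuple(d["scheme"]["n_categories"]),
        )
        cov = CovariateSpec(
            age_center=d["covariates"]["age_center"],
            age_scale=d["covariates"]["age_scale"],
            year_levels=tuple(d["covariates"]["year_levels"]),
        )
        costs = {}
        for s, tp in d["costs"].items():
            costs[s] = (
                None
                if tp is None
                else TwoPartParams(
                    np.array(tp["use_coef"]),
                    np.array(tp["mean_coef"]),
                    tp["shape"],
                    None if tp["year_levels"] is None else tuple(tp["year_levels"]),
                )
            )
        return cls(
            n_states=d["n_states"],
            scheme=scheme,
            covariates=cov,
            init_coef=np.array(d["init_coef"]),
            trans_coef=np.array(d["trans_coef"]),
            ind_logits=[np.array(a) for a in d["ind_logits"]],
            costs=costs,
        )

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "LatentModelParams":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def n_free_params(self, services: tuple[str, ...] = ("hospital",)) -> int:
        """Free parameters of the jointly estimated model (for AIC/BIC)."""
        L, M = self.n_living, self.n_states
        n = (L - 1) * self.covariates.n_init
        n += L * (M - 1) * self.covariates.n_trans
        n += sum(L * (k - 1) for k in self.scheme.n_categories)
        for s in services:
            tp = self.costs.get(s)
            if tp is not None:
                n += tp.use_coef.size + tp.mean_coef.size + 1
        return n
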