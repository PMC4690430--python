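"""Run configuration for the end-to-end pipeline (YAML round-trip)."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class PanelConfig:
    n: int = 2000
    start_year: int = 1995
    n_years: int = 13
    survey_interval: int = 3
    refresh_year: int | None = 2002
    seed: int = 10


@dataclass
class ModelConfig:
    n_states: int = 4
    tol: float = 1.0e-7
    max_iter: int = 500
    n_restarts: int = 1
    init: str = "kmeans"
    seed: int = 20


@dataclass
class ScenarioConfig:
    ids: list[str] = field(
        default_factory=lambda: ["baseline", "1o", "1++", "2o", "2+", "2++", "3o", "3+", "3++"]
    )
    target_year: int = 2050


@dataclass
class ProjectionConfig:
    cohort_size: float = 10_000.0
    max_stock_age: int = 95
    end_year: int = 2050


@dataclass
class RunConfig:
    """Seeds, sample design, model settings and scenario list for one run."""

    truth_seed: int = 1
    output_dir: str = "outputs"
    panel: PanelConfig = field(default_factory=PanelConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    scenarios: ScenarioConfig = field(default_factory=ScenarioConfig)
    projection: ProjectionConfig = field(default_factory=ProjectionConfig)

    _SECTIONS = {"panel": PanelConfig, "model": ModelConfig,
                 "scenarios": ScenarioConfig, "projection": ProjectionConfig}

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d or {})
        kwargs = {}
        for section, klass in cls._SECTIONS.items():
            sub = d.pop(section, {})
            if sub is None:
                sub = {}
            unknown = set(sub) - {f for f in klass.__dataclass_fields__}
            if unknown:
                raise ValueError(f"unknown keys in config section '{section}': {sorted(unknown)}")
            kwargs[section] = klass(**sub)
        top_fields = {"truth_seed", "output_dir"}
        unknown = set(d) - top_fields
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        return cls(**{**d, **kwargs})

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
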