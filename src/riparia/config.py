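"""Pipeline configuration: schema, validation and hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .grids import GridSpec
from .scenario import ScenarioConfig
from .synthetic import LandscapeConfig

__all__ = ["PipelineConfig", "ConfigError"]

REQUIRED_SEEDS = ("landscape", "species", "surveys", "conflict", "households", "scenario")


class ConfigError(ValueError):
    """Configuration failed validation before any stage ran."""


@dataclass
class PipelineConfig:
    grid: GridSpec = field(default_factory=lambda: GridSpec(100, 100, 30.0))
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    seeds: dict = field(default_factory=dict)
    p_enter: float = 0.05
    n_birds: int = 30
    n_mammals: int = 20
    n_households: int = 461
    n_presence: int = 308
    n_absence: int = 97
    n_production_points: int = 50

    def validate(self) -> None:
        missing = [s for s in REQUIRED_SEEDS if s not in self.seeds]
        if missing:
            raise ConfigError(f"all seeds must be explicit; missing: {missing}")
        for k, v in self.seeds.items():
            if not isinstance(v, int):
                raise ConfigError(f"seed {k!r} must be an integer, got {v!r}")
        if not 0 < self.p_enter < 1:
            raise ConfigError("p_enter must lie in (0, 1)")
        self.landscape.validate()

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = dict(d)
        if "grid" in kwargs:
            kwargs["grid"] = GridSpec(**kwargs["grid"])
        if "landscape" in kwargs:
            kwargs["landscape"] = LandscapeConfig(**kwargs["landscape"])
        if "scenario" in kwargs:
            kwargs["scenario"] = ScenarioConfig(**kwargs["scenario"])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()
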