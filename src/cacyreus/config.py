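"""Run configuration: one seed, nested per-stage sections, YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .landscape import LandscapeConfig


@dataclass
class DesignConfig:
    bands: list[tuple[float, float]] = field(
        default_factory=lambda: [(500.0, 1000.0), (1000.0, 1500.0),
                                 (1500.0, 2000.0)])
    n_per_band: int = 25
    visits: int = 3
    eligibility: str | None = "open"

    def __post_init__(self) -> None:
        self.bands = [tuple(b) for b in self.bands]


@dataclass
class TruthConfig:
    mixture: str = "ZIP"
    psi: float = 0.5
    beta: dict[str, float] | None = None   # None -> package defaults
    alpha: dict[str, float] | None = None


@dataclass
class ModelConfig:
    covariate_candidates: list[str] = field(
        default_factory=lambda: ["bio01", "bio04", "pel_abu", "pel_neigh",
                                 "wood", "eco", "grass"])
    collinearity_threshold: float = 0.7
    mixtures: list[str] = field(default_factory=lambda: ["P", "NB", "ZIP"])
    k_trunc_cap: int = 8000


@dataclass
class GofConfig:
    replicates: int = 1000
    enabled: bool = True


@dataclass
class MaxentConfig:
    covariates: list[str] = field(
        default_factory=lambda: ["bio01", "bio04", "pel_abu", "pel_neigh"])
    buffer_km: float = 2.5
    n_background: int = 1000
    replicas: int = 100
    train_fraction: float = 0.8
    reg_multiplier: float = 1.0
    n_points: int = 138
    bias_strength: float = 1.0


@dataclass
class ScenarioConfig:
    delta_bio01: float = 1.5
    pel_multiplier: float = 0.5
    n_elevation_bins: int = 10


@dataclass
class RunConfig:
    """Everything a full simulate-fit-diagnose-project run needs.

    All randomness flows from ``seed``; each stage receives an
    independent child stream spawned from it.
    """

    seed: int = 0
    outdir: str = "runs/demo"
    log_level: str = "INFO"
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    design: DesignConfig = field(default_factory=DesignConfig)
    truth: TruthConfig = field(default_factory=TruthConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    gof: GofConfig = field(default_factory=GofConfig)
    maxent: MaxentConfig = field(default_factory=MaxentConfig)
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["landscape"]["elev_range"] = list(d["landscape"]["elev_range"])
        d["design"]["bands"] = [list(b) for b in d["design"]["bands"]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        sections = {"landscape": LandscapeConfig, "design": DesignConfig,
                    "truth": TruthConfig, "model": ModelConfig,
                    "gof": GofConfig, "maxent": MaxentConfig,
                    "scenario": ScenarioConfig}
        for name, klass in sections.items():
            if name in kwargs and isinstance(kwargs[name], dict):
                kwargs[name] = klass(**kwargs[name])
        if isinstance(kwargs.get("landscape"), LandscapeConfig):
            lc = kwargs["landscape"]
            lc.elev_range = tuple(lc.elev_range)
        known = {f.name for f in fields(cls)}
        unknown = set(kwargs) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
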