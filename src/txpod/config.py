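"""Pipeline-wide configuration.

Every numeric threshold used by the filtering, modeling, and tPOD stages
lives here so that a single YAML file can reconfigure a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigError


@dataclass
class PrefilterConfig:
    """Trend-test and fold-change gate applied before curve fitting."""

    p_threshold: float = 0.05
    fc_threshold: float = 1.5
    n_permutations: int = 999
    two_sided: bool = True

    def validate(self) -> None:
        if self.n_permutations < 99:
            raise ConfigError("n_permutations must be >= 99")
        if not 0 < self.p_threshold < 1:
            raise ConfigError("p_threshold must be in (0, 1)")
        if self.fc_threshold < 1:
            raise ConfigError("fc_threshold must be >= 1")


@dataclass
class BmcConfig:
    """Curve-fit, benchmark-response, and post-filter settings."""

    bmr_k: float = 1.0
    bmr_sd_source: str = "model"  # "model" (fitted sigma) or "control" (control-group SD)
    confidence: float = 0.95
    alpha_nested: float = 0.05
    fit_p_min: float = 0.1
    bmcu_bmcl_max: float = 40.0
    max_iterations: int = 250
    n_starts: int = 5

    def validate(self) -> None:
        if self.bmr_sd_source not in ("model", "control"):
            raise ConfigError("bmr_sd_source must be 'model' or 'control'")
        if not 0 < self.confidence < 1:
            raise ConfigError("confidence must be in (0, 1)")
        if self.bmr_k <= 0:
            raise ConfigError("bmr_k must be > 0")


@dataclass
class TpodConfig:
    """Parameters of the five tPOD derivation methods."""

    percentile: float = 0.05
    percentile_interpolated: bool = False
    n_rank: int = 25
    mode_min_genes: int = 5
    mode_grid_points: int = 512
    lcrd_ratio: float = 1.66
    geneset_min_genes: int = 3
    geneset_min_frac: float = 0.05

    def validate(self) -> None:
        if not 0 < self.percentile < 1:
            raise ConfigError("percentile must be in (0, 1)")
        if self.lcrd_ratio <= 1:
            raise ConfigError("lcrd_ratio must be > 1")


@dataclass
class PhysiologyConfig:
    """Adult-human physiological constants for the steady-state TK model.

    Units: flows in L/day/kg body weight, liver mass in g/kg body weight,
    hepatocellularity in 1e6 cells per gram of liver.
    """

    hepatic_blood_flow: float = 24.0
    gfr: float = 2.2
    liver_mass_per_kg: float = 25.7
    hepatocellularity: float = 110.0

    def validate(self) -> None:
        for name, value in asdict(self).items():
            if value <= 0:
                raise ConfigError(f"physiology field {name} must be > 0")


@dataclass
class MonteCarloConfig:
    """Population-variability sampling for the Css quantile."""

    n_draws: int = 1000
    cv: float = 0.3
    quantile: float = 0.95

    def validate(self) -> None:
        if self.n_draws < 100:
            raise ConfigError("n_draws must be >= 100")
        if self.cv < 0:
            raise ConfigError("cv must be >= 0")


@dataclass
class PipelineConfig:
    prefilter: PrefilterConfig = field(default_factory=PrefilterConfig)
    bmc: BmcConfig = field(default_factory=BmcConfig)
    tpod: TpodConfig = field(default_factory=TpodConfig)
    physiology: PhysiologyConfig = field(default_factory=PhysiologyConfig)
    mc: MonteCarloConfig = field(default_factory=MonteCarloConfig)

    def validate(self) -> None:
        for section in (self.prefilter, self.bmc, self.tpod, self.physiology, self.mc):
            section.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(
            prefilter=PrefilterConfig(**raw.get("prefilter", {})),
            bmc=BmcConfig(**raw.get("bmc", {})),
            tpod=TpodConfig(**raw.get("tpod", {})),
            physiology=PhysiologyConfig(**raw.get("physiology", {})),
            mc=MonteCarloConfig(**raw.get("mc", {})),
        )
        cfg.validate()
        return cfg

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)
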