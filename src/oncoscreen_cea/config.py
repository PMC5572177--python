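"""Pipeline configuration: one YAML/JSON-mappable object for a full run.

The config carries every scalar the analysis depends on — trial design,
hazard calibration targets, unit costs, discount rates, bootstrap and PSA
settings — so a run is fully determined by (config, master seed).  A
stable digest of the config is stamped into every output file.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .synthetic_trial import CostModel, HazardSpec, TrialDesign, calibrate_hazard

__all__ = ["AnalysisConfig", "ExtrapolationConfig", "MarkovConfig", "PipelineConfig"]


@dataclass(frozen=True)
class AnalysisConfig:
    discount_rates: tuple[float, ...] = (0.0, 0.015, 0.035)
    alpha: float = 0.05
    n_bootstrap: int = 0
    test_cost_sweep: tuple[float, ...] = (15.0, 20.0, 30.0, 40.0, 50.0)

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.discount_rates):
            raise ValueError("discount rates must be >= 0")


@dataclass(frozen=True)
class ExtrapolationConfig:
    horizon: float = 25.0
    df_grid: tuple[int, ...] = (1, 2, 3)
    screen_active_years: int = 8


@dataclass(frozen=True)
class MarkovConfig:
    start_age: int = 60
    incidence: float = 0.001
    early_fraction_screened: float = 0.39
    early_fraction_none: float = 0.26
    psa_test_cost_range: tuple[float, float] = (15.0, 50.0)
    psa_draws: int = 100
    life_table_csv: str | None = None


@dataclass(frozen=True)
class PipelineConfig:
    design: TrialDesign = field(default_factory=TrialDesign)
    hazard: HazardSpec | None = None  # None -> calibrated from the design
    costs: CostModel = field(default_factory=CostModel)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    extrapolation: ExtrapolationConfig = field(default_factory=ExtrapolationConfig)
    markov: MarkovConfig = field(default_factory=MarkovConfig)
    seed: int = 20_170_725

    def __post_init__(self) -> None:
        if self.extrapolation.horizon <= self.design.max_followup:
            raise ValueError("extrapolation horizon must exceed trial follow-up")

    def resolved_hazard(self) -> HazardSpec:
        return self.hazard if self.hazard is not None else calibrate_hazard(self.design)

    def to_dict(self) -> dict:
        return {
            "trial": {
                "design": asdict(self.design),
                "hazard": None if self.hazard is None else asdict(self.hazard),
                "costs": asdict(self.costs),
            },
            "analysis": asdict(self.analysis),
            "extrapolation": asdict(self.extrapolation),
            "markov": asdict(self.markov),
            "seed": self.seed,
        }

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        def build(klass, section):
            if section is None:
                return None
            names = {f.name for f in fields(klass)}
            kwargs = {}
            for k, v in section.items():
                if k not in names:
                    raise ValueError(f"unknown {klass.__name__} key {k!r}")
                kwargs[k] = tuple(v) if isinstance(v, list) else v
            return klass(**kwargs)

        trial = data.get("trial", {})
        return cls(
            design=build(TrialDesign, trial.get("design", {})) or TrialDesign(),
            hazard=build(HazardSpec, trial.get("hazard")),
            costs=build(CostModel, trial.get("costs", {})) or CostModel(),
            analysis=build(AnalysisConfig, data.get("analysis", {})) or AnalysisConfig(),
            extrapolation=build(ExtrapolationConfig, data.get("extrapolation", {})) or ExtrapolationConfig(),
            markov=build(MarkovConfig, data.get("markov", {})) or MarkovConfig(),
            seed=data.get("seed", 20_170_725),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict(), default=list)), fh,
                           sort_keys=False)
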