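"""Run configuration: one structured YAML file with strict validation."""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, field_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class InputsConfig(_Strict):
    quarters: list[Path] = []
    hierarchy: Optional[Path] = None


class TargetConfig(_Strict):
    synonyms: list[str] = ["epirubicin"]
    roles: list[Literal["PS", "SS", "C", "I"]] = ["PS"]

    @field_validator("synonyms", "roles")
    @classmethod
    def _non_empty(cls, v):
        if not v:
            raise ValueError("must be non-empty")
        return v


class WindowConfig(_Strict):
    start: str = "2014Q1"
    end: str = "2023Q1"


class ThresholdConfig(_Strict):
    min_a: int = 3
    z: float = 1.96
    ror_lo_cutoff: float = 1.0
    prr_lo_cutoff: float = 1.0
    ic_low_cutoff: float = 0.0
    ebgm05_cutoff: float = 2.0
    band_edges: tuple[float, float, float] = (0.0, 1.5, 3.0)


class StatsConfig(_Strict):
    zero_cell: Literal["correct", "strict"] = "correct"
    yates: bool = True
    ic_variance: Literal["delta", "bayes"] = "delta"


class InjectedPair(_Strict):
    drug: str
    pt: str
    theta: float


class SimulateConfig(_Strict):
    n_cases: int = 20_000
    seed: int = 0
    duplicate_rate: float = 0.0
    n_soc: int = 8
    injected: list[InjectedPair] = []


class RunConfig(_Strict):
    inputs: InputsConfig = InputsConfig()
    target: TargetConfig = TargetConfig()
    window: WindowConfig = WindowConfig()
    thresholds: ThresholdConfig = ThresholdConfig()
    stats: StatsConfig = StatsConfig()
    output: Path = Path("out")
    simulate: SimulateConfig = SimulateConfig()

    def signal_thresholds(self):
        from .signals import Thresholds

        t = self.thresholds
        return Thresholds(t.min_a, t.z, t.ror_lo_cutoff, t.prr_lo_cutoff,
                          t.ic_low_cutoff, t.ebgm05_cutoff, tuple(t.band_edges))


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration (unknown keys rejected)."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)
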