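"""JSON configuration: one document with `signal`, `controller`, `pig`,
`cohort` and `scenario` sections, each mirroring the corresponding module's
parameter object field-for-field.  Unknown keys are rejected."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field

from .controller import ControllerConfig
from .harness import ScenarioConfig
from .pig_sim import PigParams
from .signal_features import SignalConfig

__all__ = ["CohortConfig", "RefitConfig", "load_config", "default_config_json"]


class CohortConfig(BaseModel):
    """Cohort sampling (`cohort:` section); the seed lives in `scenario:`."""

    n: int = Field(default=12, ge=1)
    cv: float = Field(default=0.10, ge=0, description="coefficient of variation of jittered parameters")
    weight_mean: float = Field(default=30.8, gt=0)
    weight_sd: float = Field(default=0.7, ge=0)


class RefitConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    signal: SignalConfig = Field(default_factory=SignalConfig)
    controller: ControllerConfig = Field(default_factory=ControllerConfig)
    pig: dict = Field(default_factory=dict, description="overrides of PigParams fields")
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    scenario: ScenarioConfig = Field(default_factory=ScenarioConfig)

    def pig_params(self) -> PigParams:
        valid = {f.name for f in dataclasses.fields(PigParams)}
        unknown = set(self.pig) - valid
        if unknown:
            raise ValueError(f"unknown pig parameter(s): {sorted(unknown)}")
        return PigParams(**self.pig)

    def to_json(self) -> str:
        return json.dumps(self.model_dump(), indent=2)


def load_config(path: str | Path) -> RefitConfig:
    """Load and validate a JSON config file; raises before any run on error."""
    with open(path) as fh:
        data = json.load(fh)
    return RefitConfig.model_validate(data)


def default_config_json() -> str:
    cfg = RefitConfig()
    out = cfg.model_dump()
    out["pig"] = dataclasses.asdict(PigParams())
    return json.dumps(out, indent=2)
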