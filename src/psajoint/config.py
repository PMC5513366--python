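"""Experiment configuration: schema-validated, YAML round-trippable."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .model import PopulationParameters
from .posterior import SamplerSettings
from .simulate import DesignSpec

__all__ = ["ExperimentConfig", "load_config", "dump_config"]


class PopulationBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    r_pop: float = Field(default=0.054, gt=0)
    psa0_pop: float = Field(default=73.9, gt=0)
    eps_pop: float = Field(default=0.34, gt=0, lt=1)
    tesc_pop: float = Field(default=138.0, gt=0)
    d_fixed: float = 0.046
    delta_elim_fixed: float = 0.23
    omega_r: float = Field(default=0.098, gt=0)
    omega_psa0: float = Field(default=1.57, gt=0)
    omega_eps: float = Field(default=1.34, gt=0)
    omega_tesc: float = Field(default=0.64, gt=0)
    sigma: float = Field(default=0.38, gt=0)
    lambda_w: float = Field(default=3800.0, gt=0)
    k_w: float = Field(default=1.19, gt=0)
    beta_link: float = 0.32
    link_type: str = "current"

    def build(self) -> PopulationParameters:
        return PopulationParameters(**self.model_dump())


class DesignBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_subjects: int = Field(default=200, ge=1)
    visit_interval: float = Field(default=21.0, gt=0)
    max_followup: float = Field(default=913.0, gt=0)
    admin_censor: float | None = None

    def build(self, seed: int) -> DesignSpec:
        return DesignSpec(seed=seed, **self.model_dump())


class SamplerBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_walkers: int = Field(default=20, ge=8)
    warmup: int = Field(default=250, ge=1)
    thin: int = Field(default=10, ge=1)
    init_scale: float = Field(default=0.2, gt=0)

    def build(self) -> SamplerSettings:
        return SamplerSettings(**self.model_dump())


class HorizonBlock(BaseModel):
    """Horizon grid in months: start, stop inclusive, step."""

    model_config = ConfigDict(extra="forbid")

    start: float = 2.0
    stop: float = 18.0
    step: float = 0.5

    @model_validator(mode="after")
    def _check(self):
        if not (self.step > 0 and self.stop >= self.start > 0):
            raise ValueError("horizon grid requires 0 < start <= stop and step > 0")
        return self

    def grid_months(self):
        import numpy as np
        n = int(round((self.stop - self.start) / self.step))
        return np.round(self.start + self.step * np.arange(n + 1), 9)


class ExperimentConfig(BaseModel):
    """Full simulate -> predict -> evaluate experiment description."""

    model_config = ConfigDict(extra="forbid")

    population: PopulationBlock = PopulationBlock()
    design: DesignBlock = DesignBlock()
    sampler: SamplerBlock = SamplerBlock()
    horizons: HorizonBlock = HorizonBlock()
    landmarks_months: list[float] = [0.0, 6.0, 12.0, 18.0]
    L: int = Field(default=200, ge=1)
    seed: int = 20170717


def load_config(path) -> ExperimentConfig:
    """Load and validate a YAML config; unknown keys are rejected.

    An empty file yields the documented defaults (the reference
    current-PSA joint model and the standard simulation design).
    """
    raw = Path(path).read_text()
    data = yaml.safe_load(raw)
    if data is None:
        data = {}
    return ExperimentConfig.model_validate(data)


def dump_config(config: ExperimentConfig, path=None) -> str:
    """Serialize to YAML; load(dump(c)) == c."""
    text = yaml.safe_dump(config.model_dump(), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text
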