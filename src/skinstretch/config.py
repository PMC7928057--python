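"""Run configuration: validated defaults for every pipeline stage.

A run config aggregates the stimulus parameters (6 Hz, 2 N pulse), the 14 x
15 trial design, the device model (motors, load, control loop at 100 Hz) and
the analysis settings (1000 Hz upsampling, 10%-of-max onsets, fit mode,
test tail).  Configs load from JSON; unknown keys and out-of-range values
are rejected with the offending fields named.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import device as dev
from .stimulus import DESIGN_LAGS_MS, PulseSpec

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class StimulusSection(_Section):
    frequency: float = Field(6.0, gt=0)
    peak: float = Field(2.0, gt=0)
    sample_rate: float = Field(100.0, gt=0)
    pre_silence: float = Field(0.2, ge=0)
    post_silence: float = Field(0.3, ge=0)

    def to_pulse_spec(self) -> PulseSpec:
        return PulseSpec(**self.model_dump())


class DesignSection(_Section):
    lags: list[int] = Field(default_factory=lambda: list(DESIGN_LAGS_MS))
    reps: int = Field(15, ge=1)
    seed: int = 12345


class MotorSection(_Section):
    force_constant: float = Field(1.0, gt=0)
    terminal_resistance: float = Field(2.1, gt=0)
    electrical_time_constant: float = Field(1e-3, gt=0)
    max_current: float = Field(4.0, gt=0)

    def to_params(self) -> dev.MotorParams:
        return dev.MotorParams(**self.model_dump())


class LoadSection(_Section):
    stiffness: float = Field(300.0, ge=0)
    damping: float = Field(2.0, ge=0)
    moving_mass: float = Field(0.01, gt=0)
    coupling_stiffness: float = Field(500.0, gt=0)

    def to_load(self) -> dev.SkinLoad:
        return dev.SkinLoad(**self.model_dump())


class ControlSection(_Section):
    kp: float = Field(0.5, ge=0)
    ki: float = Field(2.0, ge=0)
    kd: float = Field(0.0, ge=0)
    sample_rate: float = Field(100.0, gt=0)
    noise_sd: float = Field(0.03, ge=0)
    seed: int = 0
    feedforward: bool = True

    def to_control(self) -> dev.ControlConfig:
        return dev.ControlConfig(**self.model_dump())


class AnalysisSection(_Section):
    upsample_rate: float = Field(1000.0, gt=0)
    smooth_window: int = Field(11, ge=1)
    onset_threshold: float = Field(0.10, gt=0, lt=1)
    fit_mode: Literal["mle", "proportions-ls"] = "mle"
    tail: Literal["less", "greater", "two-sided"] = "less"

    @model_validator(mode="after")
    def _odd_window(self) -> "AnalysisSection":
        if self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be odd")
        return self


class CohortSection(_Section):
    n_participants: int = Field(3, ge=1)
    mu: float = -18.37
    jnd: float = Field(25.15, gt=0)
    lapse: float = Field(0.0, ge=0, lt=0.5)
    between_participant_sd_mu: float = Field(0.0, ge=0)
    between_participant_sd_jnd: float = Field(0.0, ge=0)


class RunConfig(_Section):
    """Validated configuration for a full simulation + analysis run."""

    stimulus: StimulusSection = StimulusSection()
    design: DesignSection = DesignSection()
    motor_v: MotorSection = MotorSection()
    motor_h: MotorSection = MotorSection()
    load: LoadSection = LoadSection()
    control: ControlSection = ControlSection()
    analysis: AnalysisSection = AnalysisSection()
    cohort: CohortSection = CohortSection()

    @model_validator(mode="after")
    def _consistent_rates(self) -> "RunConfig":
        if self.stimulus.sample_rate != self.control.sample_rate:
            raise ValueError(
                "stimulus.sample_rate must equal control.sample_rate "
                f"({self.stimulus.sample_rate} != {self.control.sample_rate})"
            )
        if self.analysis.upsample_rate < self.control.sample_rate:
            raise ValueError("analysis.upsample_rate must be >= the control rate")
        return self

    def device_config(self) -> dev.DeviceConfig:
        return dev.DeviceConfig(
            motor_v=self.motor_v.to_params(),
            motor_h=self.motor_h.to_params(),
            load=self.load.to_load(),
            control=self.control.to_control(),
        )

    def with_seed(self, seed: int) -> "RunConfig":
        """Copy with all stage seeds derived from one master seed."""
        data = self.model_dump()
        data["design"]["seed"] = int(seed)
        data["control"]["seed"] = int((seed * 2654435761 + 1) % (2**31 - 1))
        return RunConfig.model_validate(data)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON config; an empty file yields all defaults."""
    text = Path(path).read_text(encoding="utf-8").strip()
    data = json.loads(text) if text else {}
    return RunConfig.model_validate(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(config.model_dump(), indent=2) + "\n", encoding="utf-8"
    )


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the effective configuration (provenance)."""
    canonical = json.dumps(config.model_dump(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]
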