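"""Run configuration: schema, defaults, loading and validation.

Configurations are YAML (or JSON) mappings validated against a pydantic
schema with unknown keys rejected.  Every block mirrors one engine object
and has a ``build`` method producing it.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import outflow as of
from .controllers import ControllerConfig, DecisionTable, DEFAULT_BANDS
from .scenarios import EngineConfig, ScenarioSpec, default_sequence
from .vessel import (
    CurveForm,
    PressureVolumeCurve,
    VesselProfile,
    apply_subject_variation,
    design_vessel_from_curve,
    crystalloid_curve,
    whole_blood_curve,
)

__all__ = ["RunConfig", "load_config", "default_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CurveSettings(_Strict):
    form: Literal["linear", "parabolic"]
    coefficients: list[float]
    valid_pressure_range: tuple[float, float]
    variability_scale: float = Field(1.0, gt=0)

    def build(self) -> VesselProfile:
        curve = PressureVolumeCurve(
            CurveForm(self.form),
            tuple(self.coefficients),
            tuple(self.valid_pressure_range),
        )
        profile = design_vessel_from_curve(curve)
        if self.variability_scale != 1.0:
            profile = apply_subject_variation(profile, self.variability_scale)
        return profile


class VesselSettings(_Strict):
    whole_blood: Optional[CurveSettings] = None
    crystalloid: Optional[CurveSettings] = None

    def build(self) -> dict[str, VesselProfile]:
        wb = (
            self.whole_blood.build()
            if self.whole_blood
            else design_vessel_from_curve(whole_blood_curve())
        )
        crys = (
            self.crystalloid.build()
            if self.crystalloid
            else design_vessel_from_curve(crystalloid_curve())
        )
        return {"whole_blood": wb, "crystalloid": crys}


class OutflowSettings(_Strict):
    map_zero_threshold: float = 30.0
    urine_threshold: float = 50.0
    urine_rate: float = 5.0
    overpressure_threshold: float = 70.0
    overpressure_reset_margin: float = 2.0
    noise_fraction: float = Field(0.05, ge=0, lt=1)
    pump_clamp: tuple[float, float] = (0.0, 600.0)
    hf_init_high: float = 120.0 / 68.0
    hf_init_low: float = 60.0 / 68.0
    hf_event: float = 255.0 / 68.0
    coag_rate_whole_blood: float = 0.05
    coag_rate_crystalloid: float = 0.02
    ramp_rate: float = 0.05
    tic_ramp_rate: float = 0.2
    clot_reset_restores_hf: bool = True

    def build(self) -> of.OutflowConfig:
        return of.OutflowConfig(**self.model_dump())


class ControllerSettings(_Strict):
    type: Literal["decision_table"] = "decision_table"
    sampling_period_s: float = Field(120.0, gt=0)
    q_max: float = Field(500.0, gt=0)
    target: float = Field(68.0, gt=0)
    bands: list[tuple[float, float]] = Field(
        default_factory=lambda: [tuple(b) for b in DEFAULT_BANDS]
    )

    def build(self) -> ControllerConfig:
        table = DecisionTable(
            bands=tuple(tuple(b) for b in self.bands),
            q_max=self.q_max,
            target=self.target,
        )
        return ControllerConfig(sampling_period=self.sampling_period_s, table=table)


class RunSettings(_Strict):
    seed: int = 0
    bleed: Literal["low", "high"] = "high"
    noise: bool = True
    # Scenario-4 non-clotting hemorrhage cap (mL/min per mmHg). The shipped
    # high-bleed value lets the bleed outgrow the pump's 500 mL/min maximum
    # over the scenario; pair low bleed with a mild cap such as 0.9.
    hf_ramp_cap: float = Field(10.0, gt=0)
    initial_pressure: float = 40.0
    initial_deficit_ml: float = 2300.0
    safety_cap_min: float = Field(60.0, gt=0)
    reset_baseline: bool = False
    scenarios: list[int] = Field(default_factory=lambda: [1, 2, 3, 4])

    @field_validator("scenarios")
    @classmethod
    def _ordered_known(cls, v: list[int]) -> list[int]:
        if not v or any(s not in (1, 2, 3, 4) for s in v) or sorted(v) != v:
            raise ValueError("scenarios must be an ordered subset of [1, 2, 3, 4]")
        return v


class RunConfig(_Strict):
    vessels: VesselSettings = Field(default_factory=VesselSettings)
    outflow: OutflowSettings = Field(default_factory=OutflowSettings)
    controller: ControllerSettings = Field(default_factory=ControllerSettings)
    run: RunSettings = Field(default_factory=RunSettings)
    output_dir: str = "resusbench_out"

    # -- builders ---------------------------------------------------------

    def engine_config(self) -> EngineConfig:
        return EngineConfig(
            target=self.controller.target,
            initial_pressure=self.run.initial_pressure,
            initial_deficit_ml=self.run.initial_deficit_ml,
            noise=self.run.noise,
        )

    def scenario_specs(self) -> list[ScenarioSpec]:
        seq = default_sequence(
            severity=self.run.bleed,
            hf_ramp_cap=self.run.hf_ramp_cap,
            safety_cap_min=self.run.safety_cap_min,
        )
        return [s for s in seq if s.id in self.run.scenarios]


def default_config() -> RunConfig:
    return RunConfig()


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = yaml.safe_load(path.read_text())
    if data is None:
        data = {}
    return RunConfig.model_validate(data)
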