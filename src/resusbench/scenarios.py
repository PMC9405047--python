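"""Scenario orchestration: chained hemorrhage/resuscitation experiments.

Four scenarios, run in succession with state carrying over, exercise a
controller against a common target MAP of 68 mmHg:

1. initial hypovolemia (MAP 40 mmHg) with a clotting hemorrhage, whole
   blood infusate;
2. a sudden massive re-bleed (tourniquet failure) then WB resuscitation;
3. the re-bleed again with a 15 mmHg vasopressor step applied immediately
   and withdrawn after 10 min;
4. crystalloid resuscitation against a non-clotting, escalating hemorrhage
   (trauma-induced coagulopathy), capped at 30 min.

Scenarios 1-3 end 15 min after the sensed MAP first reaches 99% of target
(with a safety cap); scenario 4 ends at its time cap regardless.  The
coupled loop advances the plant at 0.1 s, the outflow/record clock at 1 s,
and the controller at its own sampling period with zero-order hold.
"""

from __future__ import annotations

import dataclasses
import json
from collections import deque
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from . import outflow as of
from .controllers import Controller, ControllerConfig, DecisionTableController
from .plant import (
    DEFAULT_MAP_WINDOW,
    DEFAULT_PLANT_DT,
    PlantState,
    WaveformConfig,
    mean_pressure,
    sensed_map,
    set_vasopressor,
    step_volume,
)
from .vessel import (
    VesselProfile,
    design_vessel_from_curve,
    crystalloid_curve,
    switch_infusate,
    volume_at_pressure,
    whole_blood_curve,
)

__all__ = [
    "VasopressorSpec",
    "EventReleaseRule",
    "ScenarioSpec",
    "EngineConfig",
    "RunRecord",
    "default_profiles",
    "default_sequence",
    "initialize_run",
    "run_scenario",
    "check_termination",
    "run_sequence",
]


@dataclasses.dataclass(frozen=True)
class VasopressorSpec:
    step_mmhg: float = 15.0
    duration_min: float = 10.0


@dataclasses.dataclass(frozen=True)
class EventReleaseRule:
    """When a massive-hemorrhage event ends.

    ``map_drop_or_timeout`` (default) releases when the sensed MAP falls to
    ``map_threshold`` or after ``max_duration_min``, whichever happens
    first; ``map_drop`` and ``fixed`` use only one criterion.
    """

    mode: str = "map_drop_or_timeout"
    map_threshold: float = 40.0  # mmHg
    max_duration_min: float = 5.0

    def __post_init__(self) -> None:
        if self.mode not in ("map_drop_or_timeout", "map_drop", "fixed"):
            raise ValueError(f"unknown release mode {self.mode!r}")

    def should_release(self, sensed: float, elapsed_min: float) -> bool:
        by_map = sensed <= self.map_threshold
        by_time = elapsed_min >= self.max_duration_min
        if self.mode == "map_drop":
            return by_map
        if self.mode == "fixed":
            return by_time
        return by_map or by_time


@dataclasses.dataclass(frozen=True)
class ScenarioSpec:
    """One scenario of the chained protocol."""

    id: int
    infusate: str = "whole_blood"
    severity: str = "high"  # initial hemorrhage-factor level
    coag_enabled: bool = True
    open_with_massive_event: bool = False
    event_release: EventReleaseRule = dataclasses.field(
        default_factory=EventReleaseRule
    )
    vasopressor: Optional[VasopressorSpec] = None
    ramp_event_cap: Optional[float] = None  # HF cap; enables the ramp event
    target_fraction: float = 0.99
    stabilize_min: float = 15.0
    time_cap_min: Optional[float] = None  # hard stop (scenario 4: 30 min)
    safety_cap_min: float = 60.0  # guard for scenarios assumed to converge


@dataclasses.dataclass(frozen=True)
class EngineConfig:
    """Loop cadences and shared physiological settings."""

    target: float = 68.0  # mmHg
    plant_dt: float = DEFAULT_PLANT_DT  # s
    io_dt: float = 1.0  # s, outflow update + record cadence
    map_window: float = DEFAULT_MAP_WINDOW  # s
    initial_pressure: float = 40.0  # mmHg
    initial_deficit_ml: float = 2300.0  # whole-system volume loss at start
    vasopressor_step: float = 15.0  # mmHg
    pressure_offset: float = 0.0  # mmHg, static elevation offset
    noise: bool = True
    waveform: WaveformConfig = dataclasses.field(default_factory=WaveformConfig)


@dataclasses.dataclass
class RunRecord:
    """Sampled time series of one scenario plus its metadata."""

    frame: pd.DataFrame
    meta: dict

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def write_meta(self, path) -> None:
        Path(path).write_text(json.dumps(self.meta, indent=2, default=float))


def default_profiles(variability: float = 1.0) -> dict[str, VesselProfile]:
    """The shipped whole-blood and crystalloid vessels."""
    wb = design_vessel_from_curve(whole_blood_curve())
    crys = design_vessel_from_curve(crystalloid_curve())
    if variability != 1.0:
        from .vessel import apply_subject_variation

        wb = apply_subject_variation(wb, variability)
        crys = apply_subject_variation(crys, variability)
    return {"whole_blood": wb, "crystalloid": crys}


def default_sequence(
    severity: str, hf_ramp_cap: float, safety_cap_min: float = 60.0
) -> list[ScenarioSpec]:
    """The four-scenario protocol at a given bleed severity.

    ``hf_ramp_cap`` (mL/min per mmHg) bounds the scenario-4 non-clotting
    hemorrhage escalation and must be chosen explicitly.
    """
    common = dict(severity=severity, safety_cap_min=safety_cap_min)
    return [
        ScenarioSpec(id=1, **common),
        ScenarioSpec(id=2, open_with_massive_event=True, **common),
        ScenarioSpec(
            id=3,
            open_with_massive_event=True,
            vasopressor=VasopressorSpec(),
            **common,
        ),
        ScenarioSpec(
            id=4,
            infusate="crystalloid",
            coag_enabled=False,
            open_with_massive_event=True,
            ramp_event_cap=hf_ramp_cap,
            time_cap_min=30.0,
            **common,
        ),
    ]


def initialize_run(
    profile: VesselProfile, cfg: EngineConfig = EngineConfig()
) -> PlantState:
    """Plant state at the scripted starting pressure (default 40 mmHg)."""
    hydrostatic = cfg.initial_pressure - cfg.pressure_offset
    if hydrostatic < 0 or hydrostatic > profile.capacity_pressure:
        raise ValueError(
            f"starting pressure {cfg.initial_pressure:g} mmHg is unreachable in a "
            f"vessel spanning [{cfg.pressure_offset:g}, "
            f"{cfg.pressure_offset + profile.capacity_pressure:g}] mmHg"
        )
    return PlantState(
        active_profile=profile,
        contained_volume=volume_at_pressure(profile, hydrostatic),
        vasopressor_step=cfg.vasopressor_step,
        pressure_offset=cfg.pressure_offset,
    )


def check_termination(
    spec: ScenarioSpec,
    t_scenario_s: float,
    reached_time_s: Optional[float],
) -> bool:
    """Scenario stop rule given elapsed time and first time at 99% of target."""
    if spec.time_cap_min is not None:
        return t_scenario_s >= spec.time_cap_min * 60.0 - 1e-9
    if (
        reached_time_s is not None
        and t_scenario_s - reached_time_s >= spec.stabilize_min * 60.0 - 1e-9
    ):
        return True
    return t_scenario_s >= spec.safety_cap_min * 60.0 - 1e-9


class _Ledger:
    """Whole-run fluid bookkeeping carried across scenarios."""

    def __init__(self, initial_deficit_ml: float):
        self.cum_infused = 0.0
        self.cum_outflow = 0.0
        self.initial_deficit = initial_deficit_ml
        self.reservoir_fill = 0.0  # vessel pre-fills at infusate switches

    @property
    def deficit(self) -> float:
        return self.initial_deficit - self.cum_infused + self.cum_outflow


def run_scenario(
    spec: ScenarioSpec,
    state: PlantState,
    hemo: of.HemorrhageState,
    controller: Controller,
    outflow_cfg: of.OutflowConfig,
    cfg: EngineConfig,
    rng: Optional[np.random.Generator],
    ledger: Optional[_Ledger] = None,
) -> tuple[RunRecord, PlantState, of.HemorrhageState]:
    """Advance the coupled loop through one scenario.

    Returns the record plus the carried-over plant and hemorrhage states.
    ``rng`` drives the hemorrhage noise; pass ``None`` (or set
    ``cfg.noise=False``) for noise-free runs.
    """
    if ledger is None:
        ledger = _Ledger(cfg.initial_deficit_ml)
    substeps = int(round(cfg.io_dt / cfg.plant_dt))
    n_window = int(round(cfg.map_window / cfg.plant_dt)) + 1
    use_rng = rng if cfg.noise else None

    # Prime the sensing window with the current (steady) waveform so the
    # first controller decision sees a full 5 s of signal.
    base0 = mean_pressure(state)
    win_t = deque(
        (state.time - (n_window - i) * cfg.plant_dt for i in range(1, n_window + 1)),
        maxlen=n_window,
    )
    win_p = deque((base0 for _ in range(n_window)), maxlen=n_window)

    rows: list[tuple] = []
    t0 = state.time
    reached_time: Optional[float] = None
    event_open_time: Optional[float] = None
    event_release_time: Optional[float] = None
    vaso_off_time: Optional[float] = None
    second = 0

    while True:
        t_rel = second * cfg.io_dt
        if not np.isfinite(state.contained_volume):
            raise RuntimeError(
                f"non-finite plant state at t={state.time:.1f} s; last 60 s: "
                f"{rows[-60:]}"
            )
        sensed = sensed_map(np.array(win_t), np.array(win_p), cfg.map_window)

        # --- scripted events and vasopressor timeline --------------------
        if second == 0:
            if spec.open_with_massive_event:
                hemo = of.apply_event(hemo, of.EVENT_MASSIVE, outflow_cfg)
                event_open_time = t_rel
            elif spec.ramp_event_cap is not None:
                # non-clotting escalating hemorrhage from the start
                hemo = of.apply_event(
                    hemo, of.EVENT_RAMP, outflow_cfg, cap=spec.ramp_event_cap
                )
                event_open_time = t_rel
            if spec.vasopressor is not None:
                state = set_vasopressor(
                    dataclasses.replace(
                        state, vasopressor_step=spec.vasopressor.step_mmhg
                    ),
                    True,
                )
                vaso_off_time = t_rel + spec.vasopressor.duration_min * 60.0
        if (
            hemo.event == of.EVENT_MASSIVE
            and spec.event_release.should_release(sensed, hemo.event_elapsed_min)
        ):
            hemo = of.release_event(hemo)
            event_release_time = t_rel
            if spec.ramp_event_cap is not None:
                # the rapid loss hands over to the non-clotting escalation
                hemo = of.apply_event(
                    hemo, of.EVENT_RAMP, outflow_cfg, cap=spec.ramp_event_cap
                )
        if vaso_off_time is not None and t_rel >= vaso_off_time and state.vasopressor_on:
            state = set_vasopressor(state, False)

        # --- decisions ---------------------------------------------------
        q_in = max(controller.rate(t_rel, sensed), 0.0)
        q_hem = of.hemorrhage_rate(hemo, sensed, outflow_cfg, use_rng)
        q_ur = of.urine_rate(sensed, outflow_cfg)
        q_out = min(q_hem + q_ur, outflow_cfg.pump_clamp[1])
        overpressure = (
            hemo.event is None and sensed > outflow_cfg.overpressure_threshold
        )
        hemo = of.update_hemorrhage_factor(
            hemo, sensed, cfg.io_dt / 60.0, outflow_cfg
        )

        rows.append(
            (
                state.time,
                t_rel,
                spec.id,
                sensed,
                q_in,
                q_hem,
                q_ur,
                q_out,
                hemo.hf,
                hemo.event or "",
                overpressure,
                state.vasopressor_on,
                state.active_profile.infusate,
                state.contained_volume,
                ledger.cum_infused,
                ledger.cum_outflow,
                ledger.deficit,
            )
        )

        # Carry-over between scenarios means MAP can sit at target before the
        # scenario's scripted challenge acts; samples taken while the massive
        # re-bleed is still active therefore do not count as having reached
        # the target (the ongoing-ramp condition does count: it is the
        # scenario's permanent challenge, not a transient one).
        if (
            reached_time is None
            and hemo.event != of.EVENT_MASSIVE
            and sensed >= spec.target_fraction * cfg.target
        ):
            reached_time = t_rel
        if check_termination(spec, t_rel, reached_time):
            break

        # --- advance the plant through one IO interval -------------------
        for _ in range(substeps):
            state = step_volume(state, q_in, q_out, cfg.plant_dt)
            ledger.cum_infused += q_in * cfg.plant_dt / 60.0
            ledger.cum_outflow += q_out * cfg.plant_dt / 60.0
            win_t.append(state.time)
            win_p.append(mean_pressure(state))
        second += 1

    frame = pd.DataFrame(
        rows,
        columns=[
            "time_s",
            "t_scenario_s",
            "scenario_id",
            "sensed_map_mmHg",
            "q_infusion_mL_min",
            "q_hemorrhage_mL_min",
            "q_urine_mL_min",
            "q_outflow_mL_min",
            "hf_mL_min_mmHg",
            "event_active",
            "overpressure_active",
            "vasopressor_on",
            "active_vessel",
            "contained_volume_mL",
            "cum_infused_mL",
            "cum_outflow_mL",
            "deficit_mL",
        ],
    )
    meta = {
        "scenario_id": spec.id,
        "infusate": spec.infusate,
        "severity": spec.severity,
        "target_mmHg": cfg.target,
        "start_time_s": t0,
        "duration_s": float(frame["t_scenario_s"].iloc[-1]),
        "target_reached": reached_time is not None,
        "reached_time_s": reached_time,
        "event_open_time_s": event_open_time,
        "event_release_time_s": event_release_time,
        "overpressure_seconds": int(frame["overpressure_active"].sum()),
        "starved": state.starved,
        "overflowed": state.overflowed,
    }
    return RunRecord(frame=frame, meta=meta), state, hemo


def run_sequence(
    specs: Sequence[ScenarioSpec],
    controller_cfg: ControllerConfig,
    profiles: Optional[dict[str, VesselProfile]] = None,
    outflow_cfg: of.OutflowConfig = of.OutflowConfig(),
    cfg: EngineConfig = EngineConfig(),
    seed: int = 0,
    reset_baseline: bool = False,
    controller_factory: Optional[Callable[[ScenarioSpec], Controller]] = None,
) -> list[RunRecord]:
    """Run scenarios in succession with carry-over state.

    The infusate switch before a scenario with a different vessel preserves
    the sensed pressure (the incoming vessel is pre-filled from the
    reservoir); ``reset_baseline`` instead re-initialises the plant to the
    scripted starting pressure between scenarios.
    """
    if profiles is None:
        profiles = default_profiles()
    rng = np.random.default_rng(seed)
    ledger = _Ledger(cfg.initial_deficit_ml)
    state = initialize_run(profiles[specs[0].infusate], cfg)
    records: list[RunRecord] = []
    for i, spec in enumerate(specs):
        switch_fill = None
        if spec.infusate != state.active_profile.infusate:
            before = state.contained_volume
            state = switch_infusate(state, profiles[spec.infusate])
            switch_fill = state.contained_volume
            ledger.reservoir_fill += switch_fill
            del before
        if reset_baseline and i > 0:
            state = dataclasses.replace(
                state,
                contained_volume=volume_at_pressure(
                    state.active_profile,
                    cfg.initial_pressure - cfg.pressure_offset,
                ),
            )
        hemo = of.initial_hemorrhage_state(
            spec.severity, spec.infusate, outflow_cfg, spec.coag_enabled
        )
        if controller_factory is not None:
            controller = controller_factory(spec)
        else:
            controller = DecisionTableController(controller_cfg)
        record, state, hemo = run_scenario(
            spec, state, hemo, controller, outflow_cfg, cfg, rng, ledger
        )
        record.meta["seed"] = seed
        record.meta["sampling_period_s"] = getattr(
            controller_cfg, "sampling_period", None
        )
        record.meta["switch_fill_mL"] = switch_fill
        record.meta["reservoir_fill_mL"] = ledger.reservoir_fill
        record.meta["initial_deficit_mL"] = ledger.initial_deficit
        records.append(record)
    return records
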