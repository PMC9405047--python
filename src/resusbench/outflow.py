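"""Automated outflow logic: hemorrhage, coagulation, urine, scripted events.

The outflow pump rate is the sum of a pressure-dependent hemorrhage and a
basal urine output.  Hemorrhage is the product of the sensed MAP and a
time-varying hemorrhage factor (HF, mL/min per mmHg), perturbed by +/-5%
uniform noise.  Untouched, HF decays exponentially at an infusate-dependent
coagulation rate (clot formation); MAP below 30 mmHg makes bleeding
negligible, and MAP driven above 70 mmHg escalates HF (clots dislodged by
over-pressure), with a full clot reset 2 mmHg above that threshold.
Scripted events -- a sudden massive re-bleed or a monotone non-clotting
ramp -- override the normal HF bookkeeping until released.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np

__all__ = [
    "OutflowConfig",
    "HemorrhageState",
    "hemorrhage_rate",
    "update_hemorrhage_factor",
    "urine_rate",
    "apply_event",
    "release_event",
    "initial_hemorrhage_state",
]

EVENT_MASSIVE = "massive_hemorrhage"
EVENT_RAMP = "ramp_to_cap"
_KNOWN_EVENTS = (EVENT_MASSIVE, EVENT_RAMP)


@dataclasses.dataclass(frozen=True)
class OutflowConfig:
    """Tunable constants of the outflow engine.

    The HF initialisations are expressed as bleed rate at 68 mmHg divided by
    68: the high severity bleeds 120 mL/min at a MAP of 68 mmHg, the low
    severity 60 mL/min, and the massive-hemorrhage event 255 mL/min
    (comparable to resting femoral artery flow).
    """

    map_zero_threshold: float = 30.0  # mmHg; below this HF is effectively 0
    urine_threshold: float = 50.0  # mmHg (inclusive)
    urine_rate: float = 5.0  # mL/min
    overpressure_threshold: float = 70.0  # mmHg; HF escalates above this
    overpressure_reset_margin: float = 2.0  # mmHg; clot reset above 70 + 2
    noise_fraction: float = 0.05
    pump_clamp: tuple[float, float] = (0.0, 600.0)  # mL/min, total outflow
    hf_init_high: float = 120.0 / 68.0  # mL/min per mmHg
    hf_init_low: float = 60.0 / 68.0
    hf_event: float = 255.0 / 68.0
    coag_rate_whole_blood: float = 0.05  # 1/min exponential decay
    coag_rate_crystalloid: float = 0.02
    ramp_rate: float = 0.05  # HF units per min while over-pressurised
    tic_ramp_rate: float = 0.2  # HF units per min during the non-clotting ramp event
    clot_reset_restores_hf: bool = True

    def __post_init__(self) -> None:
        if not (
            self.map_zero_threshold
            < self.urine_threshold
            < self.overpressure_threshold
        ):
            raise ValueError("thresholds must be ordered: zero < urine < overpressure")
        if not 0.0 <= self.noise_fraction < 1.0:
            raise ValueError("noise_fraction must be in [0, 1)")
        if self.pump_clamp[0] < 0 or self.pump_clamp[1] <= self.pump_clamp[0]:
            raise ValueError("pump_clamp must be a non-negative increasing pair")

    def coag_rate(self, infusate: str) -> float:
        return (
            self.coag_rate_whole_blood
            if infusate == "whole_blood"
            else self.coag_rate_crystalloid
        )

    def hf_init(self, severity: str) -> float:
        if severity == "high":
            return self.hf_init_high
        if severity == "low":
            return self.hf_init_low
        raise ValueError(f"unknown bleed severity {severity!r}; use 'high' or 'low'")


@dataclasses.dataclass(frozen=True)
class HemorrhageState:
    """Hemorrhage factor plus the event/coagulation bookkeeping around it."""

    hf: float  # mL/min per mmHg
    hf_init: float  # scripted scenario initialisation, used by clot reset
    coag_rate: float  # 1/min
    coag_enabled: bool = True
    event: Optional[str] = None
    event_cap: Optional[float] = None  # HF cap for the ramp event
    event_elapsed_min: float = 0.0
    time_since_clot_reset_min: float = 0.0

    def __post_init__(self) -> None:
        if self.hf < 0:
            raise ValueError("hemorrhage factor must be non-negative")


def initial_hemorrhage_state(
    severity: str, infusate: str, cfg: OutflowConfig, coag_enabled: bool = True
) -> HemorrhageState:
    """Scenario-start state: HF from the severity, decay from the infusate."""
    return HemorrhageState(
        hf=cfg.hf_init(severity),
        hf_init=cfg.hf_init(severity),
        coag_rate=cfg.coag_rate(infusate),
        coag_enabled=coag_enabled,
    )


def _effective_hf(state: HemorrhageState, map_mmhg: float, cfg: OutflowConfig) -> float:
    if map_mmhg < cfg.map_zero_threshold:
        return 0.0
    if state.event == EVENT_MASSIVE:
        return cfg.hf_event
    return state.hf


def hemorrhage_rate(
    state: HemorrhageState,
    map_mmhg: float,
    cfg: OutflowConfig,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Hemorrhage pump rate in mL/min: ``MAP * HF_effective * (1 + u)``.

    ``u`` is uniform on +/- ``noise_fraction`` when ``rng`` is given, zero
    otherwise.  The result is clamped to the pump range.
    """
    if map_mmhg < 0:
        raise ValueError("MAP must be non-negative")
    rate = map_mmhg * _effective_hf(state, map_mmhg, cfg)
    if rng is not None and cfg.noise_fraction > 0:
        rate *= 1.0 + rng.uniform(-cfg.noise_fraction, cfg.noise_fraction)
    lo, hi = cfg.pump_clamp
    return min(max(rate, lo), hi)


def urine_rate(map_mmhg: float, cfg: OutflowConfig) -> float:
    """Basal urine output: fixed rate at or above the threshold, else zero."""
    if map_mmhg < 0:
        raise ValueError("MAP must be non-negative")
    return cfg.urine_rate if map_mmhg >= cfg.urine_threshold else 0.0


def update_hemorrhage_factor(
    state: HemorrhageState, map_mmhg: float, dt_min: float, cfg: OutflowConfig
) -> HemorrhageState:
    """Advance HF over ``dt_min`` minutes under the sensed MAP.

    Ordering of the rules (events bypass everything else):

    * massive-hemorrhage event: HF frozen (the event overrides it anyway);
    * ramp event: HF grows linearly to its cap, coagulation suppressed;
    * MAP above threshold + margin: clot reset -- decay clock zeroed and HF
      restored to at least its scenario initialisation -- plus escalation;
    * MAP above threshold: HF escalates at ``ramp_rate``;
    * MAP in the mid band: exponential coagulation decay (if enabled).

    Below the zero threshold HF is left untouched: bleeding is suppressed in
    :func:`hemorrhage_rate`, not forgotten, so it resumes if MAP recovers.
    """
    if dt_min <= 0:
        raise ValueError("dt_min must be positive")
    if state.event == EVENT_MASSIVE:
        return dataclasses.replace(
            state, event_elapsed_min=state.event_elapsed_min + dt_min
        )
    if state.event == EVENT_RAMP:
        cap = state.event_cap if state.event_cap is not None else math.inf
        return dataclasses.replace(
            state,
            hf=min(state.hf + cfg.tic_ramp_rate * dt_min, cap),
            event_elapsed_min=state.event_elapsed_min + dt_min,
        )
    if map_mmhg > cfg.overpressure_threshold + cfg.overpressure_reset_margin:
        hf = max(state.hf, state.hf_init) if cfg.clot_reset_restores_hf else state.hf
        return dataclasses.replace(
            state,
            hf=hf + cfg.ramp_rate * dt_min,
            time_since_clot_reset_min=0.0,
        )
    if map_mmhg > cfg.overpressure_threshold:
        return dataclasses.replace(state, hf=state.hf + cfg.ramp_rate * dt_min)
    if map_mmhg > cfg.map_zero_threshold and state.coag_enabled:
        return dataclasses.replace(
            state,
            hf=state.hf * math.exp(-state.coag_rate * dt_min),
            time_since_clot_reset_min=state.time_since_clot_reset_min + dt_min,
        )
    return state


def apply_event(
    state: HemorrhageState,
    event: str,
    cfg: OutflowConfig,
    cap: Optional[float] = None,
) -> HemorrhageState:
    """Activate a scripted event.

    ``massive_hemorrhage`` replaces the effective HF with ``cfg.hf_event``
    until released; ``ramp_to_cap`` switches HF to monotone growth toward
    ``cap`` (required) with coagulation disabled.
    """
    if event not in _KNOWN_EVENTS:
        raise ValueError(f"unknown event {event!r}; known: {_KNOWN_EVENTS}")
    if state.event == event:
        raise ValueError(f"event {event!r} is already active")
    if event == EVENT_RAMP:
        if cap is None:
            raise ValueError("ramp_to_cap requires an explicit HF cap")
        return dataclasses.replace(
            state, event=event, event_cap=float(cap), event_elapsed_min=0.0,
            coag_enabled=False,
        )
    return dataclasses.replace(state, event=event, event_elapsed_min=0.0)


def release_event(state: HemorrhageState, restart_coagulation: bool = True) -> HemorrhageState:
    """End the active event, restoring scripted HF behaviour.

    After a massive re-bleed the wound is assumed fresh: HF returns to its
    scenario initialisation and the coagulation clock restarts.
    """
    if state.event is None:
        return state
    was_ramp = state.event == EVENT_RAMP
    hf = state.hf_init if state.event == EVENT_MASSIVE else state.hf
    return dataclasses.replace(
        state,
        event=None,
        event_cap=None,
        event_elapsed_min=0.0,
        hf=hf,
        coag_enabled=(restart_coagulation if was_ramp else state.coag_enabled),
        time_since_clot_reset_min=0.0,
    )
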