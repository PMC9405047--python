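"""Hydraulic plant: volume integration, pulsatile pressure, sensed MAP.

The plant couples a hydrostatic vessel (see :mod:`resusbench.vessel`) with
infusion and outflow pumps.  Volume is integrated with explicit Euler at a
fixed step; the arterial waveform is the hydrostatic pressure plus a static
elevation offset, an optional vasopressor step, and a zero-mean pulsatile
component, so the mean over whole beats is exactly the non-pulsatile sum.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .vessel import VesselProfile, pressure_at_volume

__all__ = [
    "PlantState",
    "WaveformConfig",
    "MAPSeries",
    "step_volume",
    "instantaneous_pressure",
    "mean_pressure",
    "pulse_waveform",
    "sensed_map",
    "set_vasopressor",
]

#: Default plant integration step, s.
DEFAULT_PLANT_DT = 0.1
#: Default trailing window for the sensed (monitor) MAP, s.
DEFAULT_MAP_WINDOW = 5.0


@dataclasses.dataclass(frozen=True)
class PlantState:
    """Instantaneous simulator state.

    ``pressure_offset`` models the physical elevation of the vessels above
    the pressure transducer; ``vasopressor_step`` is the additive pressure
    rise produced by engaging the resistance branch (loop flow is constant,
    so a resistance increase appears as a pressure step).
    """

    active_profile: VesselProfile
    contained_volume: float  # mL
    time: float = 0.0  # s
    vasopressor_on: bool = False
    vasopressor_step: float = 15.0  # mmHg
    pressure_offset: float = 0.0  # mmHg
    starved: bool = False
    overflowed: bool = False

    def __post_init__(self) -> None:
        if not -1e-9 <= self.contained_volume <= self.active_profile.capacity_ml * (1 + 1e-9):
            raise ValueError(
                f"contained volume {self.contained_volume:g} mL outside "
                f"[0, {self.active_profile.capacity_ml:g}] mL"
            )


@dataclasses.dataclass(frozen=True)
class WaveformConfig:
    """Pulsatile source settings.

    ``pulse_amplitude`` is the peak-to-trough size of the zero-mean
    raised-cosine ejection pulse; ``ejection_fraction`` the fraction of the
    beat spent in ejection.  ``stroke_volume`` is descriptive of the bench
    pump and does not feed back on pressure (the loop is closed, so the
    stroke shuttles volume without net addition).
    """

    stroke_volume: float = 2.0  # mL
    pulse_rate: float = 120.0  # beats/min
    pulse_amplitude: float = 10.0  # mmHg, peak-to-trough
    sample_rate: float = 100.0  # Hz
    ejection_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.pulse_rate <= 0:
            raise ValueError("pulse_rate must be positive")
        if not 0 < self.ejection_fraction < 1:
            raise ValueError("ejection_fraction must be in (0, 1)")
        if self.sample_rate < 2 * self.pulse_rate / 60.0:
            raise ValueError(
                "sample_rate must be at least twice the pulse frequency"
            )

    @property
    def beat_period(self) -> float:
        return 60.0 / self.pulse_rate


@dataclasses.dataclass
class MAPSeries:
    """Sampled MAP trace with its controller setpoint."""

    times: np.ndarray  # s, strictly increasing
    values: np.ndarray  # mmHg
    target: float  # mmHg

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


def step_volume(
    state: PlantState, q_in: float, q_out: float, dt: float
) -> PlantState:
    """Advance volume by ``(q_in - q_out) * dt`` (rates in mL/min, dt in s).

    The volume is clamped to the physical range with starvation/overflow
    flags instead of failing, matching a reservoir that simply runs dry or
    spills.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if q_in < 0 or q_out < 0:
        raise ValueError("pump rates must be non-negative")
    v = state.contained_volume + (q_in - q_out) * dt / 60.0
    cap = state.active_profile.capacity_ml
    starved = v < 0
    overflowed = v > cap
    return dataclasses.replace(
        state,
        contained_volume=min(max(v, 0.0), cap),
        time=state.time + dt,
        starved=state.starved or starved,
        overflowed=state.overflowed or overflowed,
    )


def mean_pressure(state: PlantState) -> float:
    """Non-pulsatile pressure: hydrostatic + elevation offset + vasopressor."""
    p = pressure_at_volume(state.active_profile, state.contained_volume)
    p += state.pressure_offset
    if state.vasopressor_on:
        p += state.vasopressor_step
    return p


def pulse_waveform(t, wf: WaveformConfig):
    """Zero-mean pulsatile pressure component at time(s) ``t`` (s).

    A raised-cosine ejection pulse of duration ``ejection_fraction * beat``
    with its analytic beat-mean removed.  The integral over any whole number
    of beats is exactly zero; sampled means are also exactly zero whenever
    both the beat and the ejection phase span whole numbers of samples (true
    for the defaults: 0.5 s beat, 0.15 s ejection at 100 Hz).
    """
    t = np.asarray(t, dtype=float)
    d = wf.ejection_fraction
    phase = np.mod(t / wf.beat_period, 1.0)
    shape = np.where(
        phase < d, 0.5 * (1.0 - np.cos(2.0 * math.pi * phase / d)), 0.0
    )
    out = wf.pulse_amplitude * (shape - 0.5 * d)
    return out if out.ndim else float(out)


def instantaneous_pressure(state: PlantState, t: float, wf: WaveformConfig):
    """Raw arterial pressure at time ``t``: mean pressure + pulse."""
    return mean_pressure(state) + pulse_waveform(t, wf)


def sensed_map(times, pressures, window: float = DEFAULT_MAP_WINDOW) -> float:
    """Monitor MAP: mean of the raw waveform over the trailing window.

    ``times``/``pressures`` are parallel arrays; samples with
    ``t > t_end - window`` are averaged.  Raises if the record spans less
    than one window.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    times = np.asarray(times, dtype=float)
    pressures = np.asarray(pressures, dtype=float)
    if times.size == 0 or times[-1] - times[0] < window - 1e-9:
        span = 0.0 if times.size == 0 else float(times[-1] - times[0])
        raise ValueError(
            f"waveform spans {span:g} s but the sensing window needs {window:g} s"
        )
    mask = times > times[-1] - window + 1e-12
    return float(pressures[mask].mean())


def set_vasopressor(state: PlantState, on: bool) -> PlantState:
    """Engage or release the resistance branch; takes effect immediately."""
    return dataclasses.replace(state, vasopressor_on=bool(on))
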