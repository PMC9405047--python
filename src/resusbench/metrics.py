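"""Controller performance metrics.

Twelve quantities summarise how well a closed-loop controller held MAP at
its setpoint over a run:

* the Varvel statistics of the percentage performance error
  PE_i = (P_i - P_target) / P_target * 100 -- MDPE (bias), MDAPE
  (accuracy), wobble (intra-run variability) and divergence (least-squares
  slope of |PE| against time in minutes, scaled by 60 to %/h);
* step-response measures against the detected steady state -- relative
  overshoot, effectiveness (% of time within +/-5 mmHg of target) and rise
  time to 90% of the steady-state value;
* fluid economy -- volume efficiency (infused / outflow) and average
  infusion rate;
* the target-normalised areas between the MAP trace and the setpoint
  (over- and under-resuscitation burden, in minutes), plus the rise area
  accumulated before MAP first reaches 90% of target.

Steady state is declared at the earliest sample after which every later
sample stays within +/-5% of the tail estimate (mean of the final 10% of
samples).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np

from .plant import MAPSeries

__all__ = [
    "SteadyState",
    "PerformanceReport",
    "performance_errors",
    "varvel_summary",
    "detect_steady_state",
    "step_response_metrics",
    "volume_metrics",
    "area_metrics",
    "rise_area_to_setpoint",
    "report_for_series",
]

#: Effectiveness band around the target, mmHg.
EFFECTIVENESS_BAND = 5.0
#: Steady-state tolerance band, fraction of the steady-state value.
STEADY_STATE_BAND = 0.05
#: Fraction of the trailing samples averaged for the steady-state estimate.
STEADY_STATE_TAIL = 0.10
#: Rise thresholds, fraction of steady state (rise time) / target (rise area).
RISE_FRACTION = 0.90


@dataclasses.dataclass(frozen=True)
class SteadyState:
    value: float  # mmHg
    onset_time: Optional[float]  # s, None when not found
    found: bool


@dataclasses.dataclass
class PerformanceReport:
    """The twelve metrics for one scope (a scenario or the whole run)."""

    scope: str
    mdpe_pct: float
    mdape_pct: float
    wobble_pct: float
    divergence_pct_per_h: Optional[float]
    relative_overshoot_pct: Optional[float]
    overshoot_mmhg: Optional[float]
    effectiveness_pct: float
    efficiency_rise_time_min: Optional[float]
    volume_efficiency: Optional[float]
    average_infusion_rate_ml_min: Optional[float]
    area_above_min: float
    area_below_min: float
    rise_area_min: Optional[float] = None
    rise_area_reached: Optional[bool] = None
    steady_state_value: Optional[float] = None
    steady_state_found: bool = False
    wobble_steady_state_pct: Optional[float] = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def performance_errors(series: MAPSeries) -> np.ndarray:
    """PE_i = (P_i - target) / target * 100, in percent."""
    if series.target <= 0:
        raise ValueError("target pressure must be positive")
    return (series.values - series.target) / series.target * 100.0


def varvel_summary(series: MAPSeries) -> dict:
    """MDPE, MDAPE, wobble and divergence of a MAP trace.

    Divergence is the closed-form least-squares slope of |PE_i| against time
    in minutes, scaled by 60 to percent per hour; with fewer than two
    samples (or zero time spread) it is reported as ``None``.
    """
    pe = performance_errors(series)
    if pe.size == 0:
        raise ValueError("series is empty")
    mdpe = float(np.median(pe))
    mdape = float(np.median(np.abs(pe)))
    wobble = float(np.median(np.abs(pe - mdpe)))
    divergence = None
    if pe.size >= 2:
        t_min = series.times / 60.0
        ape = np.abs(pe)
        n = pe.size
        denom = float(np.sum(t_min**2) - np.sum(t_min) ** 2 / n)
        if denom > 0:
            num = float(np.sum(ape * t_min) - np.sum(ape) * np.sum(t_min) / n)
            divergence = 60.0 * num / denom
    return {
        "MDPE": mdpe,
        "MDAPE": mdape,
        "wobble": wobble,
        "divergence": divergence,
    }


def detect_steady_state(series: MAPSeries) -> SteadyState:
    """Locate the steady state of a MAP trace.

    The steady-state value is estimated as the mean of the final 10% of
    samples; the onset is the earliest sample after which every subsequent
    sample stays within +/-5% of that value.  ``found`` is False when even
    the final sample violates the band (a diverging trace).
    """
    p = series.values
    if p.size < 2:
        raise ValueError("steady-state detection needs at least 2 samples")
    tail = max(1, int(math.ceil(p.size * STEADY_STATE_TAIL)))
    value = float(p[-tail:].mean())
    band = STEADY_STATE_BAND * abs(value)
    in_band = np.abs(p - value) <= band
    if not in_band[-1]:
        return SteadyState(value=value, onset_time=None, found=False)
    # earliest index from which the trace never leaves the band again
    out = np.flatnonzero(~in_band)
    onset_idx = 0 if out.size == 0 else int(out[-1]) + 1
    return SteadyState(
        value=value, onset_time=float(series.times[onset_idx]), found=True
    )


def step_response_metrics(series: MAPSeries, ss: SteadyState) -> dict:
    """Overshoot, effectiveness and rise time against the steady state.

    Overshoot and rise time require a steady state and are ``None`` without
    one; effectiveness needs only the trace.  Effectiveness weights each
    interval by its duration, so irregular sampling is handled.
    """
    p = series.values
    t = series.times
    out: dict = {}
    if ss.found:
        max_p = float(p.max())
        out["overshoot_mmhg"] = max(max_p - ss.value, 0.0)
        out["relative_overshoot_pct"] = max(
            (max_p - ss.value) / ss.value * 100.0, 0.0
        )
        above = np.flatnonzero(p >= RISE_FRACTION * ss.value)
        out["efficiency_rise_time_min"] = (
            float(t[above[0]] - t[0]) / 60.0 if above.size else None
        )
    else:
        out["overshoot_mmhg"] = None
        out["relative_overshoot_pct"] = None
        out["efficiency_rise_time_min"] = None
    if p.size >= 2:
        dt = np.diff(t)
        in_band = np.abs(p[1:] - series.target) <= EFFECTIVENESS_BAND
        out["effectiveness_pct"] = float(dt[in_band].sum() / dt.sum() * 100.0)
    else:
        out["effectiveness_pct"] = (
            100.0 if abs(p[0] - series.target) <= EFFECTIVENESS_BAND else 0.0
        )
    return out


def volume_metrics(q_infusion, q_outflow, times) -> dict:
    """Volume efficiency (infused / outflow) and mean infusion rate.

    Rates are mL/min sampled at ``times`` (s); volumes are trapezoid
    integrals.  Efficiency is ``None`` when nothing flowed out.
    """
    q_in = np.asarray(q_infusion, dtype=float)
    q_out = np.asarray(q_outflow, dtype=float)
    t_min = np.asarray(times, dtype=float) / 60.0
    infused = float(np.trapezoid(q_in, t_min))
    outflow = float(np.trapezoid(q_out, t_min))
    return {
        "volume_efficiency": (infused / outflow) if outflow > 0 else None,
        "average_infusion_rate_ml_min": float(q_in.mean()) if q_in.size else None,
        "total_infused_ml": infused,
        "total_outflow_ml": outflow,
    }


def _signed_area_terms(series: MAPSeries) -> np.ndarray:
    """Per-interval (P_i - target) * dt_i / target, dt in minutes, i >= 2."""
    if series.times.size < 2:
        raise ValueError("area metrics need at least 2 samples")
    dt_min = np.diff(series.times) / 60.0
    if np.any(dt_min <= 0):
        raise ValueError("times must be strictly increasing")
    return (series.values[1:] - series.target) * dt_min / series.target


def area_metrics(series: MAPSeries) -> dict:
    """Area above / below the setpoint, in minutes (magnitudes).

    Discrete right-endpoint sums of the target-normalised deviation,
    restricted to samples above (respectively below) the target.
    """
    terms = _signed_area_terms(series)
    return {
        "area_above_min": float(terms[terms > 0].sum()),
        "area_below_min": float(-terms[terms < 0].sum()),
    }


def rise_area_to_setpoint(series: MAPSeries) -> tuple[float, bool]:
    """Area below target accumulated before MAP first reaches 90% of target.

    Returns ``(area_min, reached)``; when the trace never reaches the
    threshold the full-series area is returned with ``reached=False``.
    Intended for the first scenario of a sequence, whose starting point is
    uniform across controller configurations.
    """
    threshold = RISE_FRACTION * series.target
    reached = np.flatnonzero(series.values >= threshold)
    if reached.size == 0:
        return area_metrics(series)["area_below_min"], False
    end = int(reached[0])
    if end == 0:
        return 0.0, True
    sub = MAPSeries(
        times=series.times[: end + 1],
        values=series.values[: end + 1],
        target=series.target,
    )
    return area_metrics(sub)["area_below_min"], True


def report_for_series(
    series: MAPSeries,
    q_infusion=None,
    q_outflow=None,
    scope: str = "run",
    include_rise_area: bool = False,
) -> PerformanceReport:
    """Assemble the full twelve-metric report for one MAP trace."""
    varvel = varvel_summary(series)
    ss = detect_steady_state(series) if series.values.size >= 2 else SteadyState(
        float(series.values[0]), None, False
    )
    step = step_response_metrics(series, ss)
    areas = area_metrics(series)
    vol = (
        volume_metrics(q_infusion, q_outflow, series.times)
        if q_infusion is not None and q_outflow is not None
        else {"volume_efficiency": None, "average_infusion_rate_ml_min": None}
    )
    rise_area = rise_reached = None
    if include_rise_area:
        rise_area, rise_reached = rise_area_to_setpoint(series)
    wobble_ss = None
    if ss.found and ss.onset_time is not None:
        mask = series.times >= ss.onset_time
        if mask.sum() >= 1:
            post = MAPSeries(series.times[mask], series.values[mask], series.target)
            wobble_ss = varvel_summary(post)["wobble"] if mask.sum() >= 1 else None
    return PerformanceReport(
        scope=scope,
        mdpe_pct=varvel["MDPE"],
        mdape_pct=varvel["MDAPE"],
        wobble_pct=varvel["wobble"],
        divergence_pct_per_h=varvel["divergence"],
        relative_overshoot_pct=step["relative_overshoot_pct"],
        overshoot_mmhg=step["overshoot_mmhg"],
        effectiveness_pct=step["effectiveness_pct"],
        efficiency_rise_time_min=step["efficiency_rise_time_min"],
        volume_efficiency=vol["volume_efficiency"],
        average_infusion_rate_ml_min=vol["average_infusion_rate_ml_min"],
        area_above_min=areas["area_above_min"],
        area_below_min=areas["area_below_min"],
        rise_area_min=rise_area,
        rise_area_reached=rise_reached,
        steady_state_value=ss.value if ss.found else None,
        steady_state_found=ss.found,
        wobble_steady_state_pct=wobble_ss,
    )
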