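"""Closed-loop infusion controllers.

The reference controller is a six-step decision table adapted from the
banded lookup controllers used for in-vivo goal-directed resuscitation: the
distance of the sensed MAP below the target selects a fixed fraction of the
maximum pump rate, with the fractions shrinking as the target is approached
to avoid overshoot.  Output is recomputed only at multiples of the sampling
period and held (zero-order hold) in between.

Any object with a ``rate(t, sensed_map) -> mL/min`` method bounded by
``[0, q_max]`` can be plugged into the scenario engine in its place.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Protocol

__all__ = [
    "DecisionTable",
    "ControllerConfig",
    "DecisionTableController",
    "Controller",
    "default_table",
    "decision_table_rate",
    "controller_update",
    "validate_table",
]


class Controller(Protocol):
    """Interface contract for pluggable controllers."""

    def rate(self, t: float, sensed_map: float) -> float: ...


@dataclasses.dataclass(frozen=True)
class DecisionTable:
    """Banded mapping from MAP error (target - sensed) to pump-rate fraction.

    ``bands`` are six ``(error_lower_bound_mmHg, rate_fraction)`` pairs with
    strictly decreasing bounds and non-increasing fractions; an error below
    the smallest bound (including MAP above target) maps to zero flow.
    """

    bands: tuple[tuple[float, float], ...] = dataclasses.field(
        default_factory=lambda: DEFAULT_BANDS
    )
    q_max: float = 500.0  # mL/min, infusion-pump maximum
    target: float = 68.0  # mmHg

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "bands",
            tuple((float(b), float(f)) for b, f in self.bands),
        )
        validate_table(self)


#: Shipped default bands: full rate far from target, tapering through six
#: steps to a trickle just below target and off at/above it.
DEFAULT_BANDS: tuple[tuple[float, float], ...] = (
    (25.0, 1.00),
    (15.0, 0.60),
    (10.0, 0.45),
    (5.0, 0.35),
    (2.0, 0.30),
    (0.5, 0.20),
)


def default_table(q_max: float = 500.0, target: float = 68.0) -> DecisionTable:
    return DecisionTable(bands=DEFAULT_BANDS, q_max=q_max, target=target)


def validate_table(table: DecisionTable) -> DecisionTable:
    """Enforce the six-band shape and monotonicity; raises on violation."""
    bands = table.bands
    if len(bands) != 6:
        raise ValueError(f"decision table needs exactly 6 bands, got {len(bands)}")
    bounds = [b for b, _ in bands]
    fracs = [f for _, f in bands]
    if any(b2 >= b1 for b1, b2 in zip(bounds, bounds[1:])):
        raise ValueError(f"band bounds must be strictly decreasing, got {bounds}")
    if any(f2 > f1 for f1, f2 in zip(fracs, fracs[1:])):
        raise ValueError(
            f"rate fractions must be non-increasing toward the target, got {fracs}"
        )
    if any(not 0.0 <= f <= 1.0 for f in fracs):
        raise ValueError(f"rate fractions must lie in [0, 1], got {fracs}")
    if table.q_max <= 0:
        raise ValueError("q_max must be positive")
    if table.target <= 0:
        raise ValueError("target MAP must be positive")
    return table


def decision_table_rate(table: DecisionTable, sensed_map: float) -> float:
    """Infusion rate for a sensed MAP: first band whose bound <= error."""
    if sensed_map < 0:
        raise ValueError("sensed MAP must be non-negative")
    error = table.target - sensed_map
    for bound, fraction in table.bands:
        if error >= bound:
            return fraction * table.q_max
    return 0.0


@dataclasses.dataclass(frozen=True)
class ControllerConfig:
    """Sampling period (s) and decision table for the reference controller."""

    sampling_period: float = 120.0
    table: DecisionTable = dataclasses.field(default_factory=default_table)

    def __post_init__(self) -> None:
        if self.sampling_period <= 0:
            raise ValueError("sampling_period must be positive")


def controller_update(
    cfg: ControllerConfig, t: float, sensed_map: float, held_rate: float
) -> float:
    """Zero-order-hold update rule as a pure function.

    Recomputes the table rate when ``t`` is a multiple of the sampling
    period (first update at t=0); otherwise returns ``held_rate`` unchanged.
    """
    k = t / cfg.sampling_period
    if abs(k - round(k)) * cfg.sampling_period < 1e-6:
        return decision_table_rate(cfg.table, sensed_map)
    return held_rate


class DecisionTableController:
    """Stateful wrapper: the decision table behind a zero-order hold."""

    def __init__(self, cfg: ControllerConfig):
        self.cfg = cfg
        self._held = 0.0
        self._next_update = 0.0
        self.update_count = 0

    def rate(self, t: float, sensed_map: float) -> float:
        if t >= self._next_update - 1e-9:
            self._held = decision_table_rate(self.cfg.table, sensed_map)
            self.update_count += 1
            # schedule strictly the next multiple of the period after t
            self._next_update = (
                math.floor(t / self.cfg.sampling_period + 1e-9) + 1
            ) * self.cfg.sampling_period
        return self._held

    def reset(self) -> None:
        self._held = 0.0
        self._next_update = 0.0
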