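"""Hydrostatic pressure-volume vessels.

The simulated circulatory loop stores its volume in an open, elevated
reservoir whose cross-section varies with height.  The pressure at the
bottom port of an open vessel is set purely by the hydrostatic column above
it, so a vessel can be *shaped* such that filling it with volume ``V``
produces exactly the mean arterial pressure ``MAP(V)`` of a target
compliance curve: pressure substitutes for height, and the local
cross-sectional area encodes ``dV/dP``.

Two infusate responses are modelled, emulating swine bolus-resuscitation
regressions:

* whole blood -- MAP is linear in infused volume (constant compliance), so
  the vessel is a right cylinder;
* crystalloid -- MAP is parabolic with decreasing stiffness, so the vessel
  is a funnel that widens with height.

The swine regression coefficients themselves are not published; the shipped
defaults give the whole-blood vessel an equivalent radius of 27 mm and a
crystalloid vessel spanning 0-74 mmHg, both overridable.
"""

from __future__ import annotations

import dataclasses
import enum
import math
import warnings
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "MM_H2O_PER_MMHG",
    "CurveForm",
    "PressureVolumeCurve",
    "VesselProfile",
    "VesselError",
    "VesselDesignError",
    "CapacityError",
    "design_vessel_from_curve",
    "volume_at_pressure",
    "pressure_at_volume",
    "apply_subject_variation",
    "simulate_constant_infusion",
    "switch_infusate",
    "whole_blood_curve",
    "crystalloid_curve",
]

#: Height of a water column (mm, water at ~4 degC) exerting 1 mmHg at its base.
#: The bench working fluid is tap water; override for other fluids.
MM_H2O_PER_MMHG = 13.595

#: Height resolution (mm) of the quadrature grid used for all volume integrals.
DEFAULT_DZ_MM = 0.1


class VesselError(ValueError):
    """Base error for vessel geometry and capacity violations."""


class VesselDesignError(VesselError):
    """A compliance curve cannot be realised as a physical vessel."""


class CapacityError(VesselError):
    """A requested pressure or volume exceeds the vessel capacity."""


class CurveForm(str, enum.Enum):
    LINEAR = "linear"
    PARABOLIC = "parabolic"


@dataclasses.dataclass(frozen=True)
class PressureVolumeCurve:
    """MAP (mmHg) as a polynomial function of infused volume (mL).

    ``coefficients`` are ascending polynomial coefficients: 2 for a linear
    curve, 3 for a parabolic one.  MAP must be strictly increasing in volume
    over ``valid_pressure_range``.
    """

    form: CurveForm
    coefficients: tuple[float, ...]
    valid_pressure_range: tuple[float, float]

    def __post_init__(self) -> None:
        form = CurveForm(self.form)
        object.__setattr__(self, "form", form)
        coeffs = tuple(float(c) for c in self.coefficients)
        object.__setattr__(self, "coefficients", coeffs)
        expected = 2 if form is CurveForm.LINEAR else 3
        if len(coeffs) != expected:
            raise VesselDesignError(
                f"{form.value} curve needs exactly {expected} coefficients, "
                f"got {len(coeffs)}"
            )
        p_min, p_max = self.valid_pressure_range
        if not p_min < p_max:
            raise VesselDesignError(
                f"valid_pressure_range must be increasing, got ({p_min}, {p_max})"
            )
        # Strict monotonicity of MAP(V) over the valid range.  The slope of a
        # quadratic is linear in V, so checking both range endpoints suffices.
        if form is CurveForm.LINEAR:
            if coeffs[1] <= 0.0:
                raise VesselDesignError(
                    f"MAP(V) is non-increasing (slope={coeffs[1]:g} mmHg/mL); "
                    "curve is not invertible"
                )
            return
        for p in (p_min, p_max):
            v = self.volume(p)
            slope = self.dpressure_dvolume(v)
            if not slope > 0.0:
                raise VesselDesignError(
                    f"MAP(V) is non-increasing at P={p:g} mmHg (V={v:g} mL, "
                    f"slope={slope:g} mmHg/mL); curve is not invertible there"
                )

    # -- evaluation -------------------------------------------------------

    def pressure(self, volume_ml):
        """MAP at infused volume (polynomial evaluation)."""
        v = np.asarray(volume_ml, dtype=float)
        out = np.zeros_like(v)
        for c in reversed(self.coefficients):
            out = out * v + c
        return out if out.ndim else float(out)

    def dpressure_dvolume(self, volume_ml):
        """Local stiffness dMAP/dV in mmHg/mL."""
        v = np.asarray(volume_ml, dtype=float)
        c = self.coefficients
        if self.form is CurveForm.LINEAR:
            out = np.full_like(v, c[1])
        else:
            out = c[1] + 2.0 * c[2] * v
        return out if out.ndim else float(out)

    def volume(self, pressure_mmhg):
        """Invert MAP(V): volume (mL) producing the given pressure.

        For the parabolic form the root on the increasing branch (below the
        vertex) is returned.
        """
        p = np.asarray(pressure_mmhg, dtype=float)
        c = self.coefficients
        if self.form is CurveForm.LINEAR:
            out = (p - c[0]) / c[1]
        else:
            disc = c[1] ** 2 + 4.0 * c[2] * (p - c[0])
            if np.any(disc < 0):
                raise VesselDesignError(
                    "pressure outside the invertible range of the parabolic curve"
                )
            out = (-c[1] + np.sqrt(disc)) / (2.0 * c[2])
        return out if out.ndim else float(out)


@dataclasses.dataclass(frozen=True)
class VesselProfile:
    """Radius-vs-height profile of a vessel.

    ``radius_fn`` maps height z (mm above the loop port, where z=0 gives
    P=0) to the local radius in mm; it must be positive over
    ``[0, height_max]``.  ``variability_scale`` is a dimensionless multiplier
    on the equivalent radius used to emulate subject variability; contained
    volume at a given pressure scales with its square.

    The contained-volume integral V(z) = int_0^z pi r(s)^2 ds is evaluated
    once on a fixed trapezoid grid (``dz_mm`` resolution) and both the P->V
    and V->P maps are linear interpolations of that grid, which makes them
    exact inverses of each other.
    """

    infusate: str
    radius_fn: Callable[[np.ndarray], np.ndarray]
    height_max: float
    variability_scale: float = 1.0
    hydro_constant: float = MM_H2O_PER_MMHG
    dz_mm: float = DEFAULT_DZ_MM

    def __post_init__(self) -> None:
        if self.height_max <= 0:
            raise VesselDesignError("height_max must be positive")
        if self.variability_scale <= 0:
            raise VesselDesignError("variability_scale must be positive")
        if self.hydro_constant <= 0:
            raise VesselDesignError("hydro_constant must be positive")
        n = max(2, int(round(self.height_max / self.dz_mm)) + 1)
        z = np.linspace(0.0, self.height_max, n)
        r = np.asarray(self.radius_fn(z), dtype=float)
        if r.shape != z.shape:
            r = np.broadcast_to(r, z.shape).astype(float)
        if not np.all(np.isfinite(r)) or np.any(r <= 0):
            bad = z[~(np.isfinite(r) & (r > 0))][0]
            raise VesselDesignError(f"radius must be positive; violated at z={bad:.3f} mm")
        cumvol = cumulative_trapezoid(math.pi * r**2, z, initial=0.0)
        object.__setattr__(self, "_z_grid", z)
        object.__setattr__(self, "_cumvol_mm3", cumvol)

    # -- derived quantities ----------------------------------------------

    @property
    def capacity_pressure(self) -> float:
        """Highest representable pressure (mmHg) = height_max / hydro_constant."""
        return self.height_max / self.hydro_constant

    @property
    def capacity_ml(self) -> float:
        """Contained volume (mL) when filled to the brim."""
        return float(self._cumvol_mm3[-1]) * self.variability_scale**2 / 1000.0

    def _volume_at_height(self, z: float) -> float:
        return float(np.interp(z, self._z_grid, self._cumvol_mm3))


def whole_blood_curve(
    radius_mm: float = 27.0,
    p_max: float = 90.0,
    hydro_constant: float = MM_H2O_PER_MMHG,
) -> PressureVolumeCurve:
    """Default linear whole-blood compliance curve.

    The slope is chosen so the designed vessel is a right cylinder of the
    given equivalent radius: dV/dP = pi r^2 h.
    """
    slope = 1000.0 / (math.pi * radius_mm**2 * hydro_constant)  # mmHg per mL
    return PressureVolumeCurve(CurveForm.LINEAR, (0.0, slope), (0.0, p_max))


def crystalloid_curve(p_max: float = 74.0) -> PressureVolumeCurve:
    """Default parabolic crystalloid compliance curve.

    MAP(V) = 0.034 V - (34/9e6) V^2 reaches 68 mmHg at 3000 mL with
    monotonically decreasing stiffness (vertex at 4500 mL / 76.5 mmHg), i.e.
    each additional mmHg costs progressively more fluid, as observed for
    crystalloid boluses.
    """
    return PressureVolumeCurve(
        CurveForm.PARABOLIC, (0.0, 0.034, -34.0 / 9.0e6), (0.0, p_max)
    )


def design_vessel_from_curve(
    curve: PressureVolumeCurve,
    hydro_constant: float = MM_H2O_PER_MMHG,
    infusate: str | None = None,
    dz_mm: float = DEFAULT_DZ_MM,
) -> VesselProfile:
    """Shape a vessel so that filling it reproduces a compliance curve.

    Substituting z = P * hydro_constant turns the inverted curve V(P) into a
    volume-vs-height law whose derivative fixes the local cross-section:
    r(z) = sqrt(dV/dz / pi).  A linear curve yields a constant radius
    (cylinder); a parabolic curve a funnel.

    Raises :class:`VesselDesignError` if the curve slope is non-positive
    anywhere in its valid range (the construction requires dV/dz > 0).
    """
    p_min, p_max = curve.valid_pressure_range
    # dV/dP in mL/mmHg, probed across the full valid range.
    probe = np.linspace(p_min, p_max, 512)
    slopes = curve.dpressure_dvolume(curve.volume(probe))
    if np.any(slopes <= 0):
        p_bad = float(probe[np.asarray(slopes) <= 0][0])
        raise VesselDesignError(
            f"curve has non-positive dMAP/dV at P={p_bad:.3f} mmHg; "
            "dV/dz would be undefined there"
        )
    if infusate is None:
        infusate = (
            "whole_blood" if curve.form is CurveForm.LINEAR else "crystalloid"
        )

    def radius_fn(z: np.ndarray) -> np.ndarray:
        p = np.clip(np.asarray(z, dtype=float) / hydro_constant, p_min, p_max)
        dvdp_ml = 1.0 / np.asarray(curve.dpressure_dvolume(curve.volume(p)))
        # mL/mmHg -> mm^3/mm of height, then area -> radius.
        dvdz = dvdp_ml * 1000.0 / hydro_constant
        return np.sqrt(dvdz / math.pi)

    return VesselProfile(
        infusate=infusate,
        radius_fn=radius_fn,
        height_max=p_max * hydro_constant,
        hydro_constant=hydro_constant,
        dz_mm=dz_mm,
    )


def volume_at_pressure(profile: VesselProfile, pressure_mmhg: float) -> float:
    """Contained volume (mL) when the port pressure equals ``pressure_mmhg``."""
    if pressure_mmhg < 0:
        raise VesselError(f"pressure must be non-negative, got {pressure_mmhg:g}")
    if pressure_mmhg > profile.capacity_pressure * (1 + 1e-12):
        raise CapacityError(
            f"pressure {pressure_mmhg:g} mmHg exceeds vessel capacity "
            f"{profile.capacity_pressure:g} mmHg"
        )
    z = min(pressure_mmhg * profile.hydro_constant, profile.height_max)
    return profile._volume_at_height(z) * profile.variability_scale**2 / 1000.0


def pressure_at_volume(profile: VesselProfile, volume_ml: float) -> float:
    """Port pressure (mmHg) for a contained volume (inverse hydrostatic map)."""
    if volume_ml < -1e-9:
        raise VesselError(f"volume must be non-negative, got {volume_ml:g}")
    cap = profile.capacity_ml
    if volume_ml > cap * (1 + 1e-12):
        raise CapacityError(
            f"volume {volume_ml:g} mL exceeds vessel capacity {cap:g} mL"
        )
    v_mm3 = max(volume_ml, 0.0) * 1000.0 / profile.variability_scale**2
    z = float(np.interp(v_mm3, profile._cumvol_mm3, profile._z_grid))
    return z / profile.hydro_constant


def apply_subject_variation(profile: VesselProfile, scale: float) -> VesselProfile:
    """Rescale the equivalent radius; the P-V slope scales with ``scale**2``."""
    if scale <= 0:
        raise VesselError(f"variability scale must be positive, got {scale:g}")
    return dataclasses.replace(
        profile, variability_scale=profile.variability_scale * scale
    )


def simulate_constant_infusion(
    profile: VesselProfile,
    rate_ml_min: float,
    p_start: float,
    p_end: float,
    dt_s: float = 0.1,
) -> pd.DataFrame:
    """Characterisation trace: infuse at a constant rate, record pressure.

    Mirrors the bench characterisation protocol (constant 500 mL/min fill
    with the circulating pump off).  Returns a frame with columns
    ``infused_volume_mL`` and ``pressure_mmHg``; empty if ``p_start == p_end``.
    A target beyond capacity truncates the trace with a warning.
    """
    if rate_ml_min <= 0:
        raise VesselError("infusion rate must be positive")
    if p_end < p_start:
        raise VesselError("p_end must be >= p_start")
    if p_end > profile.capacity_pressure:
        warnings.warn(
            f"target pressure {p_end:g} mmHg exceeds capacity "
            f"{profile.capacity_pressure:g} mmHg; trace truncated",
            stacklevel=2,
        )
        p_end = profile.capacity_pressure
    if p_end <= p_start:
        return pd.DataFrame(columns=["infused_volume_mL", "pressure_mmHg"])
    v0 = volume_at_pressure(profile, p_start)
    v1 = volume_at_pressure(profile, p_end)
    dv = rate_ml_min * dt_s / 60.0
    volumes = np.arange(v0, v1, dv)
    volumes = np.append(volumes, v1)
    pressures = [pressure_at_volume(profile, v) for v in volumes]
    return pd.DataFrame(
        {"infused_volume_mL": volumes - v0, "pressure_mmHg": pressures}
    )


def switch_infusate(state, to_profile: VesselProfile):
    """Swap the plant's active vessel, preserving the sensed pressure.

    The new vessel is pre-filled (from the external reservoir) to the exact
    volume that reproduces the current port pressure, so the pressure trace
    is continuous across the switch.  Returns the updated plant state; the
    fill volume drawn from the reservoir is available from the state delta.
    """
    pressure = pressure_at_volume(state.active_profile, state.contained_volume)
    if pressure > to_profile.capacity_pressure:
        raise CapacityError(
            f"cannot switch: current pressure {pressure:g} mmHg exceeds target "
            f"vessel capacity {to_profile.capacity_pressure:g} mmHg"
        )
    if to_profile is state.active_profile:
        return state
    v_to = volume_at_pressure(to_profile, pressure)
    return dataclasses.replace(
        state, active_profile=to_profile, contained_volume=v_to
    )
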