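"""Vessel geometry: design from compliance curves, hydrostatic P<->V maps."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from resusbench import (
    CapacityError,
    CurveForm,
    PressureVolumeCurve,
    VesselDesignError,
    VesselError,
    apply_subject_variation,
    design_vessel_from_curve,
    pressure_at_volume,
    simulate_constant_infusion,
    switch_infusate,
    volume_at_pressure,
    whole_blood_curve,
    crystalloid_curve,
)
from resusbench.plant import PlantState
from resusbench.vessel import MM_H2O_PER_MMHG


class TestCurveValidation:
    def test_linear_needs_two_coefficients(self):
        with pytest.raises(VesselDesignError, match="2 coefficients"):
            PressureVolumeCurve(CurveForm.LINEAR, (0.0, 0.03, 1.0), (0.0, 70.0))

    def test_parabolic_needs_three_coefficients(self):
        with pytest.raises(VesselDesignError, match="3 coefficients"):
            PressureVolumeCurve(CurveForm.PARABOLIC, (0.0, 0.03), (0.0, 70.0))

    def test_zero_slope_rejected(self):
        # a pressure plateau has no invertible volume
        with pytest.raises(VesselDesignError, match="non-increasing"):
            PressureVolumeCurve(CurveForm.LINEAR, (0.0, 0.0), (0.0, 70.0))

    def test_parabolic_beyond_vertex_rejected(self):
        # default crystalloid coefficients peak at 76.5 mmHg
        with pytest.raises(VesselDesignError):
            PressureVolumeCurve(
                CurveForm.PARABOLIC, (0.0, 0.034, -34.0 / 9e6), (0.0, 80.0)
            )


class TestDesignFromCurve:
    def test_linear_curve_gives_27mm_cylinder(self, wb_profile, cylinder_ml_per_mmhg):
        # slope chosen so dV/dP = pi * 27^2 * h => constant r = 27 mm
        z = np.linspace(0.0, wb_profile.height_max, 50)
        radii = np.asarray(wb_profile.radius_fn(z))
        assert np.allclose(radii, 27.0, atol=1e-9)
        # and the realised compliance matches the hydrostatic-column arithmetic
        assert volume_at_pressure(wb_profile, 1.0) == pytest.approx(
            cylinder_ml_per_mmhg, rel=1e-9
        )

    def test_parabolic_curve_gives_widening_funnel(self, crys_profile):
        z = np.linspace(0.0, crys_profile.height_max, 50)
        radii = np.asarray(crys_profile.radius_fn(z))
        assert np.all(np.diff(radii) > 0)

    def test_flat_region_rejected_with_location(self):
        # a curve whose stiffness hits zero inside the range cannot be built
        with pytest.raises(VesselDesignError, match="non-positive"):
            design_vessel_from_curve(_ZeroSlopeCurve(whole_blood_curve()))

    def test_design_reproduces_curve_within_half_mmhg(self, crys_profile):
        """Filling the designed vessel reproduces the input compliance curve."""
        curve = crystalloid_curve()
        trace = simulate_constant_infusion(crys_profile, 500.0, 1.0, 70.0)
        v0 = volume_at_pressure(crys_profile, 1.0)
        expected = np.asarray(
            curve.pressure(v0 + trace["infused_volume_mL"].to_numpy())
        )
        dev = np.max(np.abs(trace["pressure_mmHg"].to_numpy() - expected))
        assert dev < 0.5


class _ZeroSlopeCurve:
    """Wraps a curve but reports zero stiffness at the top of its range."""

    def __init__(self, inner):
        self.form = inner.form
        self.valid_pressure_range = inner.valid_pressure_range
        self._inner = inner

    def volume(self, p):
        return self._inner.volume(p)

    def dpressure_dvolume(self, v):
        out = np.asarray(self._inner.dpressure_dvolume(v), dtype=float).copy()
        if out.ndim:
            out[-1] = 0.0
        return out


class TestHydrostaticMaps:
    def test_volume_at_10mmhg_matches_column_arithmetic(
        self, wb_profile, cylinder_ml_per_mmhg
    ):
        # pi * 27^2 * 10 * 13.595 mm^3 = 311.36 mL
        assert volume_at_pressure(wb_profile, 10.0) == pytest.approx(
            10.0 * cylinder_ml_per_mmhg, rel=1e-9
        )

    def test_zero_pressure_zero_volume(self, wb_profile, crys_profile):
        assert volume_at_pressure(wb_profile, 0.0) == 0.0
        assert pressure_at_volume(crys_profile, 0.0) == 0.0

    def test_cylinder_quadrature_matches_closed_form(self, wb_profile):
        """Trapezoid volume of a constant-radius profile is analytically exact."""
        for p in (5.0, 23.4, 61.7, 89.9):
            closed = math.pi * 27.0**2 * p * MM_H2O_PER_MMHG / 1000.0
            assert volume_at_pressure(wb_profile, p) == pytest.approx(
                closed, rel=1e-9
            )

    def test_overcapacity_errors_name_the_limit(self, wb_profile):
        with pytest.raises(CapacityError, match="90"):
            volume_at_pressure(wb_profile, 95.0)
        with pytest.raises(CapacityError, match="mL"):
            pressure_at_volume(wb_profile, wb_profile.capacity_ml * 1.01)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(p=st.floats(min_value=0.0, max_value=74.0))
    def test_round_trip_identity(self, crys_profile, p):
        """pressure(volume(P)) = P within 1e-5 mmHg across the funnel."""
        assert pressure_at_volume(
            crys_profile, volume_at_pressure(crys_profile, p)
        ) == pytest.approx(p, abs=1e-5)


class TestSubjectVariation:
    def test_identity_scale(self, wb_profile):
        same = apply_subject_variation(wb_profile, 1.0)
        assert volume_at_pressure(same, 33.0) == volume_at_pressure(wb_profile, 33.0)

    @pytest.mark.parametrize("scale", [0.9, 1.1])
    def test_volume_scales_with_square_of_radius(self, wb_profile, scale):
        varied = apply_subject_variation(wb_profile, scale)
        base = volume_at_pressure(wb_profile, 10.0)
        assert volume_at_pressure(varied, 10.0) == pytest.approx(
            scale**2 * base, rel=1e-12
        )

    @pytest.mark.parametrize("scale", [-1.0, 0.0])
    def test_nonpositive_scale_rejected(self, wb_profile, scale):
        with pytest.raises(VesselError):
            apply_subject_variation(wb_profile, scale)


class TestConstantInfusion:
    def test_cylinder_40_to_68_total_volume(self, wb_profile, cylinder_ml_per_mmhg):
        trace = simulate_constant_infusion(wb_profile, 500.0, 40.0, 68.0)
        assert trace["infused_volume_mL"].iloc[-1] == pytest.approx(
            28.0 * cylinder_ml_per_mmhg, rel=1e-6
        )
        # linear response: pressure-vs-volume curvature vanishes on the
        # uniform steps (the final step is a partial volume increment)
        second = np.diff(trace["pressure_mmHg"].to_numpy()[:-1], 2)
        assert np.max(np.abs(second)) < 1e-6

    def test_funnel_response_is_concave(self, crys_profile):
        """Pressure gain per mL decreases as the funnel widens."""
        trace = simulate_constant_infusion(crys_profile, 500.0, 10.0, 70.0)
        second = np.diff(trace["pressure_mmHg"].to_numpy(), 2)
        assert np.all(second <= 1e-9)

    def test_equal_endpoints_empty_trace(self, wb_profile):
        trace = simulate_constant_infusion(wb_profile, 500.0, 50.0, 50.0)
        assert trace.empty

    def test_target_beyond_capacity_truncates_with_warning(self, wb_profile):
        with pytest.warns(UserWarning, match="truncated"):
            trace = simulate_constant_infusion(wb_profile, 500.0, 40.0, 120.0)
        assert trace["pressure_mmHg"].iloc[-1] == pytest.approx(
            wb_profile.capacity_pressure
        )


class TestInfusateSwitch:
    def test_pressure_continuous_across_switch(self, wb_profile, crys_profile):
        state = PlantState(
            active_profile=wb_profile,
            contained_volume=volume_at_pressure(wb_profile, 55.0),
        )
        switched = switch_infusate(state, crys_profile)
        assert switched.active_profile is crys_profile
        assert pressure_at_volume(
            crys_profile, switched.contained_volume
        ) == pytest.approx(55.0, abs=1e-6)

    def test_switch_to_same_profile_is_identity(self, wb_profile):
        state = PlantState(
            active_profile=wb_profile,
            contained_volume=volume_at_pressure(wb_profile, 55.0),
        )
        assert switch_infusate(state, wb_profile) is state

    def test_switch_above_target_capacity_rejected(self, wb_profile, crys_profile):
        state = PlantState(
            active_profile=wb_profile,
            contained_volume=volume_at_pressure(wb_profile, 80.0),
        )
        with pytest.raises(CapacityError, match="capacity"):
            switch_infusate(state, crys_profile)

    @pytest.mark.parametrize("wb_volume", [300.0, 600.0, 800.0])
    def test_switchover_trace_linear_then_concave(
        self, wb_profile, crys_profile, wb_volume
    ):
        """WB fill is linear in volume; post-switch crystalloid is concave."""
        v0 = volume_at_pressure(wb_profile, 40.0)
        p_switch = pressure_at_volume(wb_profile, v0 + wb_volume)
        wb_p = [
            pressure_at_volume(wb_profile, v0 + v)
            for v in np.linspace(0, wb_volume, 25)
        ]
        assert np.max(np.abs(np.diff(wb_p, 2))) < 1e-9
        crys_trace = simulate_constant_infusion(crys_profile, 500.0, p_switch, 68.0)
        assert crys_trace["pressure_mmHg"].iloc[0] == pytest.approx(
            p_switch, abs=1e-6
        )
        assert np.all(np.diff(crys_trace["pressure_mmHg"].to_numpy(), 2) <= 1e-9)
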