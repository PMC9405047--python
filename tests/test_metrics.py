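"""Performance metrics: Varvel statistics, step response, areas, volumes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from resusbench import (
    MAPSeries,
    area_metrics,
    detect_steady_state,
    performance_errors,
    report_for_series,
    rise_area_to_setpoint,
    step_response_metrics,
    varvel_summary,
    volume_metrics,
)


def series(values, times=None, target=68.0):
    values = np.asarray(values, dtype=float)
    if times is None:
        times = np.arange(values.size, dtype=float)
    return MAPSeries(times=np.asarray(times, float), values=values, target=target)


class TestPerformanceErrors:
    def test_at_target_zero(self):
        assert performance_errors(series([68.0])) == pytest.approx([0.0])

    def test_above_and_below_target(self):
        pe = performance_errors(series([78.0, 34.0]))
        assert pe[0] == pytest.approx(10.0 / 68.0 * 100.0)
        assert pe[1] == pytest.approx(-50.0)

    def test_nonpositive_target_rejected(self):
        with pytest.raises(ValueError, match="target"):
            performance_errors(series([68.0], target=0.0))


class TestVarvel:
    def test_constant_error_series(self):
        s = series(np.full(10, 61.2))  # PE = -10% throughout
        out = varvel_summary(s)
        assert out["MDPE"] == pytest.approx(-10.0)
        assert out["MDAPE"] == pytest.approx(10.0)
        assert out["wobble"] == 0.0
        assert out["divergence"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_medians(self):
        # PE = {-2, 0, +4} percent
        values = 68.0 * (1.0 + np.array([-0.02, 0.0, 0.04]))
        out = varvel_summary(series(values))
        assert out["MDPE"] == pytest.approx(0.0)
        assert out["MDAPE"] == pytest.approx(2.0)
        assert out["wobble"] == pytest.approx(2.0)

    def test_even_count_median_is_midpoint(self):
        values = 68.0 * (1.0 + np.array([0.01, 0.03, 0.05, 0.07]))
        assert varvel_summary(series(values))["MDPE"] == pytest.approx(4.0)

    def test_divergence_of_1pct_per_minute_is_60_per_hour(self):
        """|PE| rising 1 %/min over 0..10 min gives exactly 60 %/h."""
        t_min = np.arange(0.0, 11.0)
        values = 68.0 * (1.0 + t_min / 100.0)
        out = varvel_summary(series(values, times=t_min * 60.0))
        assert out["divergence"] == pytest.approx(60.0, rel=1e-12)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_divergence_matches_least_squares_oracle(self, seed):
        """Closed-form slope equals an independent polyfit to 1e-9 relative."""
        gen = np.random.default_rng(seed)
        n = int(gen.integers(3, 60))
        t_s = np.sort(gen.uniform(0.0, 3600.0, size=n))
        t_s += np.arange(n) * 1e-3  # enforce strict increase
        values = gen.uniform(30.0, 90.0, size=n)
        out = varvel_summary(series(values, times=t_s))
        pe = (values - 68.0) / 68.0 * 100.0
        slope = np.polyfit(t_s / 60.0, np.abs(pe), 1)[0]
        assert out["divergence"] == pytest.approx(60.0 * slope, rel=1e-9, abs=1e-9)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_mdape_bounds_mdpe(self, seed):
        gen = np.random.default_rng(seed)
        values = gen.uniform(20.0, 100.0, size=int(gen.integers(1, 50)))
        out = varvel_summary(series(values))
        assert out["MDAPE"] >= abs(out["MDPE"]) - 1e-12

    def test_single_sample_divergence_missing(self):
        assert varvel_summary(series([50.0]))["divergence"] is None


class TestSteadyState:
    def test_constant_series_onset_at_start(self):
        ss = detect_steady_state(series(np.full(100, 68.0)))
        assert ss.found and ss.value == pytest.approx(68.0)
        assert ss.onset_time == 0.0

    def test_ramp_then_plateau_onset_near_plateau_start(self):
        t = np.arange(0.0, 1200.0)
        values = np.where(t < 600.0, 40.0 + (68.0 - 40.0) * t / 600.0, 68.0)
        values = values + np.where(t >= 600.0, np.sin(t / 20.0), 0.0)  # 68 +/- 1
        ss = detect_steady_state(series(values, times=t))
        assert ss.found
        assert ss.value == pytest.approx(68.0, abs=1.0)
        # forward-scan oracle: earliest index staying inside the band
        band = 0.05 * ss.value
        in_band = np.abs(values - ss.value) <= band
        out = np.flatnonzero(~in_band)
        expected_onset = t[out[-1] + 1] if out.size else t[0]
        assert ss.onset_time == expected_onset
        assert ss.onset_time <= 600.0  # the ramp enters the band before 68

    def test_diverging_series_not_found(self):
        # steep enough that the final sample leaves the tail-mean band
        t = np.arange(0.0, 600.0)
        values = 68.0 - 0.08 * t
        ss = detect_steady_state(series(values, times=t))
        assert not ss.found
        assert ss.onset_time is None


class TestStepResponse:
    def test_constant_at_target(self):
        s = series(np.full(60, 68.0))
        ss = detect_steady_state(s)
        out = step_response_metrics(s, ss)
        assert out["relative_overshoot_pct"] == 0.0
        assert out["effectiveness_pct"] == 100.0
        assert out["efficiency_rise_time_min"] == 0.0

    def test_overshoot_relative_to_steady_state(self):
        values = np.concatenate([np.array([40.0, 78.0]), np.full(98, 68.0)])
        s = series(values)
        ss = detect_steady_state(s)
        out = step_response_metrics(s, ss)
        assert out["overshoot_mmhg"] == pytest.approx(10.0)
        assert out["relative_overshoot_pct"] == pytest.approx(10.0 / 68.0 * 100.0)

    def test_effectiveness_half_time_in_band(self):
        values = np.concatenate([np.full(31, 50.0), np.full(30, 68.0)])
        s = series(values)
        out = step_response_metrics(s, detect_steady_state(s))
        assert out["effectiveness_pct"] == pytest.approx(50.0)

    def test_rise_time_to_90pct_of_steady_state(self):
        t = np.arange(0.0, 600.0)
        values = np.minimum(40.0 + 0.1 * t, 68.0)
        s = series(values, times=t)
        ss = detect_steady_state(s)
        out = step_response_metrics(s, ss)
        # first sample >= 0.9*68 = 61.2 occurs at t = 212 s
        assert out["efficiency_rise_time_min"] == pytest.approx(212.0 / 60.0)

    def test_without_steady_state_only_effectiveness(self):
        t = np.arange(0.0, 600.0)
        s = series(68.0 - 0.08 * t, times=t)
        out = step_response_metrics(s, detect_steady_state(s))
        assert out["relative_overshoot_pct"] is None
        assert out["efficiency_rise_time_min"] is None
        assert out["effectiveness_pct"] > 0.0


class TestVolumeMetrics:
    def test_ratio_of_volumes(self):
        t = np.array([0.0, 60.0])
        out = volume_metrics([300.0, 300.0], [150.0, 150.0], t)
        assert out["volume_efficiency"] == pytest.approx(2.0)

    def test_average_infusion_rate(self):
        out = volume_metrics([0.0, 100.0, 200.0], [1.0, 1.0, 1.0], [0, 60, 120])
        assert out["average_infusion_rate_ml_min"] == pytest.approx(100.0)

    def test_zero_outflow_guarded(self):
        out = volume_metrics([100.0, 100.0], [0.0, 0.0], [0.0, 60.0])
        assert out["volume_efficiency"] is None


class TestAreas:
    def test_at_target_both_zero(self):
        out = area_metrics(series(np.full(10, 68.0)))
        assert out["area_above_min"] == 0.0
        assert out["area_below_min"] == 0.0

    def test_constant_10_above_for_10_minutes(self):
        t = np.arange(0.0, 601.0, 60.0)
        out = area_metrics(series(np.full(11, 78.0), times=t))
        assert out["area_above_min"] == pytest.approx(10.0 / 68.0 * 10.0)
        assert out["area_below_min"] == 0.0

    def test_constant_10_below_for_34_minutes(self):
        t = np.arange(0.0, 34.0 * 60.0 + 1.0, 60.0)
        out = area_metrics(series(np.full(t.size, 58.0), times=t))
        assert out["area_below_min"] == pytest.approx(5.0)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_signed_area_identity(self, seed):
        """area_above - area_below equals sum(PE_i * dt_i) / 100 in minutes."""
        gen = np.random.default_rng(seed)
        n = int(gen.integers(2, 80))
        t = np.cumsum(gen.uniform(0.5, 90.0, size=n))
        values = gen.uniform(30.0, 100.0, size=n)
        s = series(values, times=t)
        out = area_metrics(s)
        pe = performance_errors(s)
        signed = float(np.sum(pe[1:] * np.diff(t) / 60.0) / 100.0)
        assert out["area_above_min"] - out["area_below_min"] == pytest.approx(
            signed, rel=1e-9, abs=1e-9
        )

    def test_time_shift_invariance(self):
        t = np.arange(0.0, 300.0, 10.0)
        values = 68.0 + 5.0 * np.sin(t / 30.0)
        a = area_metrics(series(values, times=t))
        b = area_metrics(series(values, times=t + 12345.0))
        assert a == pytest.approx(b)


class TestRiseArea:
    def test_truncates_at_90pct_of_target(self):
        t = np.arange(0.0, 1200.0, 60.0)
        values = np.minimum(40.0 + 0.04 * t, 68.0)
        s = series(values, times=t)
        area, reached = rise_area_to_setpoint(s)
        assert reached
        # oracle: area_below recomputed on the truncated prefix
        end = int(np.flatnonzero(values >= 0.9 * 68.0)[0])
        prefix = series(values[: end + 1], times=t[: end + 1])
        assert area == pytest.approx(area_metrics(prefix)["area_below_min"])

    def test_starting_at_threshold_zero(self):
        s = series(np.full(10, 0.9 * 68.0))
        area, reached = rise_area_to_setpoint(s)
        assert reached and area == 0.0

    def test_never_reaching_returns_full_area_with_flag(self):
        t = np.arange(0.0, 1800.0, 60.0)
        s = series(np.full(t.size, 50.0), times=t)
        area, reached = rise_area_to_setpoint(s)
        assert not reached
        assert area == pytest.approx(area_metrics(s)["area_below_min"])


class TestReportAssembly:
    def test_full_report_fields_consistent(self):
        t = np.arange(0.0, 1800.0)
        values = np.minimum(40.0 + 0.05 * t, 68.0)
        s = series(values, times=t)
        rep = report_for_series(
            s,
            q_infusion=np.full(t.size, 100.0),
            q_outflow=np.full(t.size, 50.0),
            scope="scenario_1",
            include_rise_area=True,
        )
        assert rep.scope == "scenario_1"
        assert rep.mdape_pct >= abs(rep.mdpe_pct)
        assert rep.volume_efficiency == pytest.approx(2.0)
        assert rep.rise_area_min is not None and rep.rise_area_reached
        assert rep.steady_state_found
        assert rep.wobble_steady_state_pct is not None
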