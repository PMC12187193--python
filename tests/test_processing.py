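"""Segmentation, OLS slope fitting, quality filter and the rate equation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aeroscope import (
    RespTrace,
    TraceConfig,
    background_slope,
    filter_slopes,
    fit_slope,
    ro2,
    segment_cycles,
    simulate_trace,
)
from aeroscope.processing import MeasurementCycle, SlopeFit


def _trace(t, o2, phase, w=0.5, m=0.5, vre=29.72, ind="F1"):
    return RespTrace(
        individual_id=ind,
        treatment_temp_c=16.0,
        time_s=np.asarray(t, float),
        o2_mg_l=np.asarray(o2, float),
        phase=np.asarray(phase, object),
        chamber_volume_l=vre,
        fish_mass_kg=w,
        displacement_l=m,
    )


def _line_trace(slope_per_min=-0.02, n=300, dt=1.0, phase="measure"):
    t = np.arange(n) * dt
    o2 = 8.0 + slope_per_min * t / 60.0
    return _trace(t, o2, [phase] * n)


class TestSegmentation:
    def test_24h_protocol_gives_72_cycles(self, basic_params):
        cfg = TraceConfig(noise_sd_mg_l=0.0)
        trace = simulate_trace(basic_params, cfg, 16.0)
        assert len(segment_cycles(trace)) == 72  # 24*60 / (5+15)

    def test_continuous_empty_trace_is_one_cycle(self):
        cfg = TraceConfig(protocol="empty_background")
        trace = simulate_trace(None, cfg, 16.0)
        cycles = segment_cycles(trace)
        assert len(cycles) == 1 and cycles[0].kind == "empty"

    def test_flush_only_trace_has_no_cycles(self):
        trace = _trace([0, 1, 2, 3], [8, 8, 8, 8], ["flush"] * 4)
        assert segment_cycles(trace) == []

    def test_schedule_fallback_for_unlabeled_traces(self):
        t = np.arange(0, 1200, 10.0)
        o2 = np.full_like(t, 8.0)
        trace = _trace(t, o2, [""] * len(t))
        cycles = segment_cycles(trace, schedule=(300.0, 900.0))
        assert len(cycles) == 1
        assert cycles[0].t_end_s == 290.0

    def test_unlabeled_without_schedule_errors(self):
        trace = _trace([0, 1, 2], [8, 8, 8], ["", "", ""])
        with pytest.raises(ValueError, match="schedule"):
            segment_cycles(trace)


class TestSlopeFit:
    def test_exact_line(self):
        trace = _line_trace(-0.02)
        fit = fit_slope(trace, segment_cycles(trace)[0])
        assert fit.slope_mg_l_min == pytest.approx(-0.02, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.n_points == 240  # first minute excluded from 300 samples

    def test_constant_trace_r2_is_zero(self):
        trace = _trace(np.arange(200.0), np.full(200, 8.0), ["measure"] * 200)
        fit = fit_slope(trace, segment_cycles(trace)[0])
        assert fit.slope_mg_l_min == 0.0
        assert fit.r_squared == 0.0

    def test_too_few_retained_samples_is_unusable(self):
        trace = _trace([0, 30, 61, 62], [8, 7.9, 7.8, 7.7], ["measure"] * 4)
        cycle = segment_cycles(trace)[0]
        assert fit_slope(trace, cycle) is None

    def test_matches_closed_form_ols_oracle(self, rng):
        """1000 random small cycles vs the closed-form normal-equation slope."""
        for _ in range(1000):
            n = rng.integers(5, 30)
            t = np.sort(rng.uniform(0, 10, n)) * 60.0 + 60.0
            t += np.arange(n) * 1e-6  # enforce strictly increasing
            y = rng.normal(8.0, 0.5, n)
            trace = _trace(t, y, ["measure"] * n)
            cycle = MeasurementCycle(0, 0, n, "measure", float(t[0]), float(t[-1]))
            fit = fit_slope(trace, cycle, exclude_initial_s=0.0)
            x = t / 60.0
            oracle = (np.sum(x * y) - n * x.mean() * y.mean()) / (
                np.sum(x * x) - n * x.mean() ** 2
            )
            assert fit.slope_mg_l_min == pytest.approx(oracle, rel=1e-12, abs=1e-12)


class TestFilter:
    def _fits(self, r2s):
        return [
            SlopeFit(-0.01, 8.0, r2, 10, i, "animal") for i, r2 in enumerate(r2s)
        ]

    def test_threshold_is_strict(self):
        kept = filter_slopes(self._fits([0.95, 0.89, 0.91]))
        assert [f.cycle_index for f in kept] == [0, 2]
        assert filter_slopes(self._fits([0.9])) == []

    def test_empty_input(self):
        assert filter_slopes([]) == []

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), max_size=30))
    def test_order_preserved_and_never_grows(self, r2s):
        fits = self._fits(r2s)
        kept = filter_slopes(fits)
        assert len(kept) <= len(fits)
        idx = [f.cycle_index for f in kept]
        assert idx == sorted(idx)

    def test_discard_fraction_grows_with_noise(self, basic_params):
        """Across a sensor-noise grid (5 seeds each) the number of cycles
        failing R^2 > 0.9 rises monotonically."""
        discards = []
        for sd in (0.0, 0.01, 0.02, 0.04):
            total = 0
            for seed in range(5):
                cfg = TraceConfig(noise_sd_mg_l=sd, seed=seed, smr_duration_h=2.0)
                trace = simulate_trace(basic_params, cfg, 10.0)
                fits = [fit_slope(trace, c) for c in segment_cycles(trace)]
                total += len(fits) - len(filter_slopes(fits))
            discards.append(total)
        assert discards[0] == 0
        assert all(a <= b for a, b in zip(discards, discards[1:]))
        assert discards[-1] > 0


class TestBackground:
    def test_noiseless_decline(self):
        cfg = TraceConfig(protocol="empty_background", background_slope_mg_l_min=0.001)
        trace = simulate_trace(None, cfg, 16.0)
        fit = background_slope(trace)
        assert fit.kind == "background"
        assert fit.slope_mg_l_min == pytest.approx(-0.001, rel=1e-9)

    def test_zero_slope_noop(self):
        cfg = TraceConfig(protocol="empty_background", background_slope_mg_l_min=0.0)
        fit = background_slope(simulate_trace(None, cfg, 16.0))
        assert fit.slope_mg_l_min == pytest.approx(0.0, abs=1e-15)

    def test_rejects_animal_phases(self):
        trace = _line_trace()
        with pytest.raises(ValueError, match="empty"):
            background_slope(trace)


class TestRO2:
    def _fit(self, slope, kind="animal"):
        return SlopeFit(slope, 8.0, 0.99, 240, 0, kind)

    def test_hand_evaluated_reference_case(self):
        trace = _trace([0, 1], [8, 8], ["measure", "measure"])
        rec = ro2(self._fit(-0.02), None, trace)
        assert rec.ro2_raw == pytest.approx(70.128, abs=1e-9)

    def test_hand_evaluated_background_case(self):
        trace = _trace([0, 1], [8, 8], ["measure", "measure"])
        rec = ro2(self._fit(-0.02), self._fit(-0.001, "background"), trace)
        expected = 70.128 - ((29.72 - 0.5) / 0.5) * 0.06 * (29.72 / 29.22)
        assert expected == pytest.approx(66.5616, abs=1e-4)
        assert rec.ro2_raw == pytest.approx(expected, rel=1e-12)

    def test_zero_slopes_give_zero(self):
        trace = _trace([0, 1], [8, 8], ["measure", "measure"])
        assert ro2(self._fit(0.0), self._fit(0.0), trace).ro2_raw == 0.0

    def test_negative_rate_flagged_not_clamped(self):
        trace = _trace([0, 1], [8, 8], ["measure", "measure"])
        rec = ro2(self._fit(-0.001), self._fit(-0.01, "background"), trace)
        assert rec.ro2_raw < 0 and rec.flagged_negative

    def test_displacement_exceeding_volume_errors(self):
        trace = _trace([0, 1], [8, 8], ["measure", "measure"], w=2.0, m=2.0, vre=29.72)
        trace.displacement_l = 30.0  # corrupt after validation
        with pytest.raises(ValueError):
            ro2(self._fit(-0.02), None, trace)

    @settings(derandomize=True, max_examples=50)
    @given(
        sa=st.floats(min_value=0.0, max_value=0.5),
        sb=st.floats(min_value=0.0, max_value=0.5),
    )
    def test_linearity_in_both_slopes(self, sa, sb):
        """RO2 is linear: coefficient ((Vre-M)/W)*60 on the animal decline and
        -(Vre/W)*60 on the background decline."""
        trace = _trace([0, 1], [8, 8], ["measure", "measure"], w=0.5, m=0.5)
        rec = ro2(self._fit(-sa), self._fit(-sb, "background"), trace)
        k = (29.72 - 0.5) / 0.5 * 60.0
        expected = k * sa - (29.72 / 0.5) * 60.0 * sb
        assert rec.ro2_raw == pytest.approx(expected, rel=1e-12, abs=1e-9)
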