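import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nfloop import (
    FeedbackConfig,
    SubjectParams,
    batch_feedback,
    despike_online,
    run_feedback_session,
    sham_trace,
    simulate_roi_run,
    thermometer_level,
)
from tests.conftest import constant_block_series


class TestDespikeOnline:
    def test_abrupt_increase_replaced_by_preceding_mean(self):
        out = despike_online([1000.0, 1001.0, 1000.0], 5000.0, k=3, m=3)
        assert out == pytest.approx((1000 + 1001 + 1000) / 3)

    def test_ordinary_fluctuation_accepted(self):
        assert despike_online([1000.0, 1001.0, 1000.0], 1002.0, k=3, m=3) == 1002.0

    def test_abrupt_decrease_accepted_one_sided(self):
        assert despike_online([1000.0, 1001.0, 1000.0], 200.0, k=3, m=3) == 200.0

    def test_first_sample_always_accepted(self):
        assert despike_online([], 12345.0) == 12345.0

    def test_window_below_two_rejected(self):
        with pytest.raises(ValueError, match="m"):
            despike_online([1.0, 2.0], 3.0, m=1)

    @given(st.lists(st.floats(900, 1100), min_size=1, max_size=10),
           st.floats(0, 5000))
    @settings(max_examples=100, deadline=None)
    def test_output_is_incoming_or_window_mean(self, history, incoming):
        out = despike_online(history, incoming)
        w = np.asarray(history[-3:])
        assert out == incoming or out == pytest.approx(w.mean())


class TestFeedbackArithmetic:
    def _run(self, design, roi1_level, roi2_level, base=1000.0):
        series = {
            "roi1_left": constant_block_series(
                design, {"baseline": base, "regulate": roi1_level}, "roi1_left"),
            "roi1_right": constant_block_series(
                design, {"baseline": base, "regulate": roi1_level}, "roi1_right"),
            "roi2": constant_block_series(
                design, {"baseline": base, "regulate": roi2_level}, "roi2"),
        }
        return run_feedback_session(series, design)

    def test_reference_subtraction(self, training_design):
        # ROI1 window 1002 over base 1000, ROI2 1001 over 1000 -> F = 2 - 1 = 1
        trace = self._run(training_design, 1002.0, 1001.0)
        assert trace.f_values[0] == pytest.approx(1.0)

    def test_equal_means_give_zero(self, training_design):
        trace = self._run(training_design, 1000.0, 1000.0)
        assert np.allclose(trace.f_values, 0.0)

    def test_global_activation_cancels_to_negative(self, training_design):
        # ROI1 rises 1, ROI2 rises 3 -> F = -2
        trace = self._run(training_design, 1001.0, 1003.0)
        assert trace.f_values[0] == pytest.approx(-2.0)


class TestThermometer:
    def test_zero_maps_to_center(self):
        assert thermometer_level(0.0, n_bars=10, scale=1.0) == 5

    def test_clamped_at_extremes(self):
        assert thermometer_level(50.0, n_bars=10, scale=1.0) == 10
        assert thermometer_level(-50.0, n_bars=10, scale=1.0) == 0

    @given(st.floats(-1e3, 1e3), st.integers(2, 20))
    @settings(max_examples=100, deadline=None)
    def test_levels_always_in_range(self, f, n_bars):
        assert 0 <= thermometer_level(f, n_bars=n_bars, scale=0.5) <= n_bars


class TestShamTrace:
    def test_deterministic_given_seed(self):
        a, b = sham_trace(60, seed=5), sham_trace(60, seed=5)
        assert np.array_equal(a.f_values, b.f_values)
        assert not a.contingent

    def test_values_stay_within_reflecting_bounds(self):
        cfg = FeedbackConfig(sham_step_sd=3.0)
        t = sham_trace(500, seed=1, config=cfg)
        assert np.all(np.abs(t.f_values) <= cfg.bound + 1e-12)

    def test_sham_ignores_brain_data(self, feedback_series, training_design):
        series = feedback_series(seed=0)
        t1 = run_feedback_session(series, training_design, mode="sham", seed=7)
        permuted = {
            roi: type(s)(subject=s.subject, session=s.session, run=s.run,
                         roi=s.roi, values=s.values[::-1].copy(), design=s.design)
            for roi, s in series.items()
        }
        t2 = run_feedback_session(permuted, training_design, mode="sham", seed=7)
        assert np.array_equal(t1.f_values, t2.f_values)

    def test_sham_uncorrelated_with_bold(self, training_design):
        """Across 100 runs the sham trace carries no contingent information."""
        p = SubjectParams()
        cors = []
        for i in range(100):
            s = simulate_roi_run(training_design, p, "roi1_left", seed=i)
            t = sham_trace(60, seed=10_000 + i)
            reg = training_design.scans_for("regulate")
            cors.append(np.corrcoef(t.f_values, s.values[reg])[0, 1])
        assert np.mean(np.abs(cors)) < 0.2


class TestFeedbackSession:
    def test_one_update_per_regulate_scan(self, feedback_series, training_design):
        trace = run_feedback_session(feedback_series(), training_design)
        assert len(trace.frame) == 60  # 3 regulate blocks x 20 scans

    def test_streaming_equals_batch_bit_identical(self, feedback_series,
                                                  training_design):
        for seed in range(20):
            series = feedback_series(seed=seed)
            stream = run_feedback_session(series, training_design)
            batch = batch_feedback(series, training_design)
            assert np.array_equal(stream.f_values, batch)

    def test_length_mismatch_rejected(self, feedback_series, training_design):
        series = feedback_series()
        s = series["roi2"]
        series["roi2"] = type(s)(subject=s.subject, session=s.session, run=s.run,
                                 roi=s.roi, values=s.values, design=s.design)
        object.__setattr__(series["roi2"], "values", s.values[:-1])
        with pytest.raises(ValueError, match="length"):
            run_feedback_session(series, training_design)

    def test_missing_roi_rejected(self, feedback_series, training_design):
        series = feedback_series()
        del series["roi2"]
        with pytest.raises(ValueError, match="missing"):
            run_feedback_session(series, training_design)

    def test_noiseless_positive_gain_gives_positive_late_f(self, training_design,
                                                           quiet_params):
        series = {
            roi: simulate_roi_run(training_design, quiet_params, roi, seed=i)
            for i, roi in enumerate(("roi1_left", "roi1_right", "roi2"))
        }
        trace = run_feedback_session(series, training_design)
        frame = trace.frame
        # last 10 updates of each regulate block sit on the response plateau
        for block in frame["block"].unique():
            late = frame[frame["block"] == block]["F"].to_numpy()[-10:]
            assert np.all(late > 0)

    def test_global_offset_timeseries_cancels(self, training_design,
                                              quiet_params):
        # noise-free so no despike replacement fires; cancellation is exact
        series = {
            roi: simulate_roi_run(training_design, quiet_params, roi, seed=i)
            for i, roi in enumerate(("roi1_left", "roi1_right", "roi2"))
        }
        base = run_feedback_session(series, training_design)
        n = len(next(iter(series.values())).values)
        offset = 2.0 * np.sin(np.linspace(0, 3 * np.pi, n))  # slow, sub-threshold
        shifted = {
            roi: type(s)(subject=s.subject, session=s.session, run=s.run,
                         roi=s.roi, values=s.values + offset, design=s.design)
            for roi, s in series.items()
        }
        out = run_feedback_session(shifted, training_design)
        assert np.allclose(base.f_values, out.f_values, atol=1e-9)

    def test_scale_equivariance(self, feedback_series, training_design):
        series = feedback_series(seed=4)
        base = run_feedback_session(series, training_design)
        c = 2.5
        scaled = {
            roi: type(s)(subject=s.subject, session=s.session, run=s.run,
                         roi=s.roi, values=c * s.values, design=s.design)
            for roi, s in series.items()
        }
        out = run_feedback_session(scaled, training_design)
        assert np.allclose(out.f_values, c * base.f_values, rtol=1e-9)
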