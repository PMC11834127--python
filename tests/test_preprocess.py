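"""Signal-chain tests: filtering, differentiation, saccade removal, blinks."""

import numpy as np
import pytest

from asemlab.preprocess import (AllMissingError, TraceLengthError,
                                butterworth_gain_squared, central_difference,
                                detect_blinks, detect_saccades, lowpass_filter,
                                preprocess_cursor, preprocess_eye,
                                remove_and_interpolate, saccade_sample_labels)
from asemlab.synth import inject_saccade, minimum_jerk_position
from asemlab.types import Interval, RawTrace, SaccadeInterval

RATE = 1000.0


def _trace(x, rate=RATE, mask=None):
    n = len(x)
    return RawTrace(time=np.arange(n) / rate, x=np.asarray(x, float),
                    y=np.zeros(n), rate=rate, mask=mask)


class TestLowpassFilter:
    def test_dc_gain_is_one(self):
        out = lowpass_filter(np.full(2000, 3.0), RATE, 15.0)
        assert np.allclose(out, 3.0, atol=1e-12)

    def test_long_constant_mean_preserved(self):
        out = lowpass_filter(np.full(5000, 7.5), RATE, 15.0)
        assert abs(out.mean() - 7.5) / 7.5 < 1e-9

    def test_linearity(self, rng):
        a = rng.normal(size=3000)
        b = rng.normal(size=3000)
        lhs = lowpass_filter(a + b, RATE, 15.0)
        rhs = lowpass_filter(a, RATE, 15.0) + lowpass_filter(b, RATE, 15.0)
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_sinusoid_attenuation_matches_design(self):
        # 50 Hz sine through the 15 Hz eye-position filter: the measured
        # steady-state amplitude must match the squared (forward-backward)
        # magnitude response of the designed second-order filter.
        t = np.arange(4000) / RATE
        out = lowpass_filter(np.sin(2 * np.pi * 50.0 * t), RATE, 15.0)
        mid = out[1000:3000]
        measured = (mid.max() - mid.min()) / 2.0
        expected = butterworth_gain_squared(RATE, 15.0, 50.0)
        assert measured == pytest.approx(expected, rel=0.05)

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError):
            lowpass_filter(np.zeros(100), 60.0, 30.0)

    def test_short_series_rejected(self):
        with pytest.raises(TraceLengthError):
            lowpass_filter(np.zeros(5), RATE, 15.0)


class TestCentralDifference:
    def test_exact_on_linear(self):
        t = np.arange(1000) / RATE
        v = central_difference(8.0 * t, RATE)
        assert np.allclose(v[1:-1], 8.0, atol=1e-9)
        # one-sided endpoints are exact for a line too
        assert v[0] == pytest.approx(8.0) and v[-1] == pytest.approx(8.0)

    def test_zero_on_constant(self):
        assert np.allclose(central_difference(np.full(100, 2.0), RATE), 0.0)

    def test_taylor_truncation_bound_on_sine(self):
        # third-derivative bound: |err| <= max|f'''| h^2 / 6
        t = np.arange(2000) / RATE
        omega = 2 * np.pi * 2.0
        v = central_difference(np.sin(omega * t), RATE)
        analytic = omega * np.cos(omega * t)
        bound = omega ** 3 / (6.0 * RATE ** 2)
        assert np.max(np.abs(v[1:-1] - analytic[1:-1])) <= bound * 1.01

    def test_too_short(self):
        with pytest.raises(TraceLengthError):
            central_difference(np.zeros(2), RATE)


def _filtered_kinematics(trace, pos_cut=15.0, vel_cut=30.0):
    fx = lowpass_filter(trace.x, trace.rate, pos_cut)
    vx = lowpass_filter(central_difference(fx, trace.rate), trace.rate, vel_cut)
    ax = lowpass_filter(central_difference(vx, trace.rate), trace.rate, vel_cut)
    return vx, ax


class TestDetectSaccades:
    def test_constant_pursuit_below_threshold(self):
        v = np.full(1000, 8.0)
        assert detect_saccades(v, np.zeros(1000), RATE) == []

    def test_single_injected_saccade_found_with_oracle_agreement(self):
        t = np.arange(2000) / RATE
        trace = _trace(0.5 * t)  # slow drift background
        trace = inject_saccade(trace, 0.5, 10.0, 0.05)
        vx, ax = _filtered_kinematics(trace)
        found = detect_saccades(vx, ax, RATE)
        assert len(found) == 1
        assert found[0].start <= 0.5 <= found[0].end
        assert found[0].peak_velocity >= 30.0
        assert found[0].peak_acceleration >= 1000.0
        labels = saccade_sample_labels(len(vx), RATE, found, pad=0.010)
        oracle = (np.abs(vx) > 30.0) & (np.abs(ax) > 1000.0)
        assert np.mean(labels == oracle) >= 0.99

    def test_two_saccades_give_two_disjoint_intervals(self):
        trace = _trace(np.zeros(2000))
        trace = inject_saccade(trace, 0.4, 5.0, 0.04)
        trace = inject_saccade(trace, 0.7, -5.0, 0.04)
        vx, ax = _filtered_kinematics(trace)
        found = detect_saccades(vx, ax, RATE)
        assert len(found) == 2
        assert found[0].end < found[1].start

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            detect_saccades(np.zeros(10), np.zeros(9), RATE)


class TestRemoveAndInterpolate:
    INTERVAL = [SaccadeInterval(0.3, 0.4, 50.0, 2000.0)]

    def test_line_through_line(self):
        x = 4.0 * np.arange(1000) / RATE
        out = remove_and_interpolate(x, self.INTERVAL, RATE)
        assert np.allclose(out, x, atol=1e-12)

    def test_gap_velocity_is_boundary_slope(self):
        # 0 deg at gap start, 2 deg at gap end, 100 ms gap -> 20 deg/s inside
        x = np.zeros(1000)
        x[400:] = 2.0
        out = remove_and_interpolate(x, [SaccadeInterval(0.3, 0.4, 50.0, 2000.0)],
                                     RATE)
        v = central_difference(out, RATE)
        assert np.allclose(v[302:399], 20.0, atol=1e-6)

    def test_empty_interval_list_is_noop(self, rng):
        x = rng.normal(size=500)
        assert np.array_equal(remove_and_interpolate(x, [], RATE), x)

    def test_outside_samples_bit_unchanged(self, rng):
        x = rng.normal(size=1000)
        out = remove_and_interpolate(x, self.INTERVAL, RATE)
        inside = (np.arange(1000) / RATE > 0.3) & (np.arange(1000) / RATE < 0.4)
        assert np.array_equal(out[~inside], x[~inside])

    def test_idempotent(self, rng):
        x = rng.normal(size=1000)
        once = remove_and_interpolate(x, self.INTERVAL, RATE)
        twice = remove_and_interpolate(once, self.INTERVAL, RATE)
        assert np.array_equal(once, twice)

    def test_out_of_bounds_interval_rejected(self):
        with pytest.raises(ValueError):
            remove_and_interpolate(np.zeros(100), [SaccadeInterval(0.05, 0.2, 50, 2000)],
                                   RATE)


class TestDetectBlinks:
    def test_no_missing_samples(self):
        assert detect_blinks(_trace(np.zeros(1000))) == []

    def test_planted_run_covered(self):
        mask = np.zeros(1000, dtype=bool)
        mask[300:450] = True  # 150 ms
        found = detect_blinks(_trace(np.zeros(1000), mask=mask), pad=0.05)
        assert len(found) == 1
        assert found[0].start <= 0.3 and found[0].end >= 0.449

    def test_merge_by_padding(self):
        mask = np.zeros(2000, dtype=bool)
        mask[300:350] = True
        mask[380:430] = True  # 30 ms apart < 2 * 50 ms padding -> merge
        assert len(detect_blinks(_trace(np.zeros(2000), mask=mask), pad=0.05)) == 1
        mask2 = np.zeros(2000, dtype=bool)
        mask2[300:350] = True
        mask2[600:650] = True  # 250 ms apart > 2 * padding -> two intervals
        assert len(detect_blinks(_trace(np.zeros(2000), mask=mask2), pad=0.05)) == 2


class TestPreprocessEye:
    def test_clean_pursuit_asem_window_identity(self, clean_cohort, analysis_cfg):
        from asemlab.kinematics import compute_asem_velocity
        cohort, truth = clean_cohort
        rec = cohort.trials[0]
        series, saccades, blinks = preprocess_eye(rec.eye, analysis_cfg)
        assert saccades == [] and blinks == []
        measured = compute_asem_velocity(series, rec.meta.onset_time)
        true = truth.trials.iloc[0].true_asem
        assert measured == pytest.approx(true, abs=1e-3)

    def test_desaccaded_velocity_below_threshold(self):
        # planted saccade on a fixation trace: after removal, no sample may
        # exceed the 30 deg/s criterion. The bridge slope is the mean removed
        # velocity over core + padding, so ample padding (20 ms) is used; at
        # the minimal 10 ms pad the bridge of a threshold-skimming saccade
        # can itself skim the threshold.
        from asemlab.config import AnalysisConfig
        cfg = AnalysisConfig(saccade_pad=0.020)
        trace = _trace(np.zeros(2000))
        trace = inject_saccade(trace, 0.8, 1.5, 0.05)
        series, saccades, _ = preprocess_eye(trace, cfg)
        assert len(saccades) == 1
        sel = (series.time > 0.1) & (series.time < 1.9)
        assert np.all(np.abs(series.vx[sel]) < 30.0)
        # default (10 ms) padding still attenuates below the un-desaccaded peak
        series_d, _, _ = preprocess_eye(trace)
        vx_raw, _ = _filtered_kinematics(trace)
        assert np.max(np.abs(series_d.vx[sel])) < np.max(np.abs(vx_raw))

    def test_all_missing_raises(self):
        trace = _trace(np.zeros(1000), mask=np.ones(1000, dtype=bool))
        with pytest.raises(AllMissingError):
            preprocess_eye(trace)


class TestPreprocessCursor:
    def test_stationary_cursor_zero_velocity(self):
        trace = _trace(np.full(120, 1.5), rate=60.0)
        series = preprocess_cursor(trace)
        assert np.allclose(series.vx, 0.0, atol=1e-9)
        assert np.allclose(series.vy, 0.0, atol=1e-9)

    def test_linear_motion_velocity(self):
        t = np.arange(120) / 60.0
        series = preprocess_cursor(_trace(5.0 * t, rate=60.0))
        assert np.allclose(series.vx[5:-5], 5.0, atol=1e-3)

    def test_bell_reach_peak_velocity_within_2pct(self):
        t = np.arange(120) / 60.0
        mt, dist, start = 0.4, 15.0, 0.8
        x = dist * minimum_jerk_position((t - start) / mt)
        series = preprocess_cursor(_trace(x, rate=60.0))
        analytic_peak = 1.875 * dist / mt
        assert np.max(np.abs(series.vx)) == pytest.approx(analytic_peak, rel=0.02)
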