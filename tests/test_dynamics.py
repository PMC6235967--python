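"""Trace extraction, smoothing, peak detection, staging, recirculation timing."""

import numpy as np
import pytest

from aoicg import dynamics as dy
from aoicg import preprocess as pp

from conftest import pearson


def _trace(values, times=None, valid=None):
    values = np.asarray(values, dtype=float)
    if times is None:
        times = np.arange(len(values), dtype=float)
    if valid is None:
        valid = np.ones(len(values), dtype=bool)
    return dy.IntensityTrace(times=times, values=values, valid=valid)


def two_gaussian_trace(delay, dt=0.06, t_end=60.0, amp2=0.4, w1=2.0, w2=5.0):
    t = np.arange(0.0, t_end, dt)
    v = np.exp(-0.5 * ((t - 13.0) / w1) ** 2) + amp2 * np.exp(
        -0.5 * ((t - 13.0 - delay) / w2) ** 2
    )
    return _trace(v, times=t)


class TestExtractTrace:
    def test_constant_stack_constant_trace(self):
        rs = pp.RegisteredStack(
            pixels=np.full((6, 8, 8), 2.5), channel="icg",
            times=np.arange(6.0), pixel_scale=1.0,
        )
        tr = dy.extract_trace(rs)
        assert np.allclose(tr.values, 2.5)

    def test_matches_true_kinetics_on_noiseless_video(self, analyzed_noiseless):
        res, truth = analyzed_noiseless
        tr = dy.extract_trace(res["icg"])
        s_true = np.array(
            [truth.composite_frame(t).mean() for t in range(len(truth.gains))]
        )
        assert pearson(tr.values[tr.valid], s_true[tr.valid]) > 0.999

    def test_blink_frames_carried_invalid(self, analyzed_noisy):
        res, truth = analyzed_noisy
        tr = dy.extract_trace(res["icg"])
        assert not tr.valid[truth.blinks].any()
        assert np.isnan(tr.values[truth.blinks]).all()

    def test_roi_outside_coverage_rejected(self, analyzed_noiseless):
        res, _ = analyzed_noiseless
        big = pp.Rect(0, 10_000, 0, 10_000)
        with pytest.raises(ValueError):
            dy.extract_trace(res["icg"], big)


class TestSmoothTrace:
    def test_window_one_is_identity(self):
        tr = _trace(np.random.default_rng(0).normal(size=50))
        out = dy.smooth_trace(tr, 1)
        assert np.array_equal(out.values, tr.values)

    def test_constant_trace_unchanged(self):
        out = dy.smooth_trace(_trace(np.full(40, 3.0)), 15)
        assert np.allclose(out.values, 3.0)

    def test_matches_direct_convolution_oracle(self):
        """Interior samples equal an explicit weighted-average computation."""
        rng = np.random.default_rng(7)
        tr = _trace(rng.normal(size=200))
        window, sigma = 15, 15 / 6.0
        out = dy.smooth_trace(tr, window)
        offs = np.arange(-7, 8)
        k = np.exp(-0.5 * (offs / sigma) ** 2)
        for i in (30, 100, 150):
            expected = np.sum(k * tr.values[i + offs]) / np.sum(k)
            assert out.values[i] == pytest.approx(expected, rel=1e-12)

    def test_variance_reduction_on_white_noise(self):
        rng = np.random.default_rng(1)
        tr = _trace(rng.normal(size=5000))
        out = dy.smooth_trace(tr, 15)
        k = np.exp(-0.5 * (np.arange(-7, 8) / 2.5) ** 2)
        k /= k.sum()
        expected_factor = np.sum(k**2)
        observed = np.var(out.values[20:-20]) / np.var(tr.values)
        assert observed == pytest.approx(expected_factor, rel=0.15)

    def test_invalid_samples_excluded_from_windows(self):
        v = np.ones(30)
        v[10] = 100.0
        valid = np.ones(30, bool)
        valid[10] = False
        out = dy.smooth_trace(_trace(v, valid=valid), 5)
        assert np.nanmax(out.values[valid]) == pytest.approx(1.0)


class TestDetectPeaks:
    def test_two_gaussians_give_two_peaks_at_known_spacing(self):
        delay = 18.3
        tr = two_gaussian_trace(delay)
        peaks = dy.detect_peaks(dy.smooth_trace(tr, 15), 0.05, 5.0)
        assert len(peaks) == 2
        assert dy.recirculation_time(peaks) == pytest.approx(delay, abs=0.06)

    def test_monotone_trace_not_measurable(self):
        tr = _trace(np.linspace(0, 1, 100))
        with pytest.raises(dy.NotMeasurableError):
            dy.detect_peaks(tr, 0.05, 5.0)

    def test_secondary_below_prominence_threshold_leaves_one_peak(self):
        tr = two_gaussian_trace(18.0, amp2=0.03)
        peaks = dy.detect_peaks(dy.smooth_trace(tr, 15), 0.05, 5.0)
        assert len(peaks) == 1

    def test_peak_count_monotone_in_prominence(self):
        tr = two_gaussian_trace(18.0, amp2=0.4)
        sm = dy.smooth_trace(tr, 15)
        counts = []
        for frac in (0.02, 0.1, 0.3, 0.6):
            try:
                counts.append(len(dy.detect_peaks(sm, frac, 5.0)))
            except dy.NotMeasurableError:
                counts.append(0)
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestStagesAndRecirculation:
    def test_stage3_starts_after_last_peak(self, analyzed_noiseless):
        res, _ = analyzed_noiseless
        peaks = dy.detect_peaks(res["smoothed"], 0.05, 5.0)
        stages = dy.define_stages(res["smoothed"], peaks)
        assert stages.stage3_found
        assert stages.stage3[0] > peaks.peak_times[-1]

    def test_rising_phase_ends_at_primary_peak(self, analyzed_noiseless):
        res, _ = analyzed_noiseless
        peaks = dy.detect_peaks(res["smoothed"], 0.05, 5.0)
        stages = dy.define_stages(res["smoothed"], peaks)
        assert stages.stage1_rising[1] == pytest.approx(peaks.peak_times[0])
        assert stages.stage1_rising[0] < stages.stage1_rising[1]
        a, b = stages.stage1
        assert a <= stages.stage1_rising[0] or a <= stages.stage1_rising[1] <= b

    def test_stage3_onset_within_observed_clinical_band(self, analyzed_noiseless):
        """Plausibility: onset lands 16–102 s after the primary peak."""
        res, _ = analyzed_noiseless
        peaks = dy.detect_peaks(res["smoothed"], 0.05, 5.0)
        stages = dy.define_stages(res["smoothed"], peaks)
        offset = stages.stage3[0] - peaks.peak_times[0]
        assert 16.0 <= offset <= 102.0

    def test_no_stable_window_flags_stage3(self):
        t = np.arange(0.0, 30.0, 0.06)
        v = np.exp(-0.5 * ((t - 10) / 2) ** 2) + 0.05 * t  # keeps drifting
        tr = _trace(v, times=t)
        peaks = dy.detect_peaks(dy.smooth_trace(tr, 15), 0.05, 5.0)
        stages = dy.define_stages(tr, peaks, stability_tol=0.001, stability_span=10.0)
        assert not stages.stage3_found

    def test_recirculation_time_is_peak_difference(self):
        peaks = dy.PeakSet(
            peak_times=np.array([10.0, 28.31]),
            peak_values=np.array([1.0, 0.4]),
            prominences=np.array([1.0, 0.4]),
        )
        assert dy.recirculation_time(peaks) == pytest.approx(18.31)

    def test_single_peak_not_measurable(self):
        peaks = dy.PeakSet(
            peak_times=np.array([10.0]),
            peak_values=np.array([1.0]),
            prominences=np.array([1.0]),
        )
        with pytest.raises(dy.NotMeasurableError):
            dy.recirculation_time(peaks)

    def test_estimate_invariant_to_affine_trace_rescale(self):
        tr = two_gaussian_trace(20.0)
        sm = dy.smooth_trace(tr, 15)
        t1 = dy.recirculation_time(dy.detect_peaks(sm, 0.05, 5.0))
        sm2 = dy.IntensityTrace(sm.times, 7.0 * sm.values - 3.0, sm.valid)
        t2 = dy.recirculation_time(dy.detect_peaks(sm2, 0.05, 5.0))
        assert t1 == pytest.approx(t2, abs=1e-9)


class TestZscore:
    def test_patient_value_against_normative_range(self):
        assert dy.zscore(19.0, 18.31, 2.98) == pytest.approx(0.23, abs=0.005)

    @pytest.mark.parametrize("x,expected", [(18.31, 0.0), (18.31 + 2.98, 1.0)])
    def test_reference_points(self, x, expected):
        assert dy.zscore(x, 18.31, 2.98) == pytest.approx(expected)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            dy.zscore(1.0, 0.0, 0.0)
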