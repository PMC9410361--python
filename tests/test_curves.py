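"""Curve characterization: smoothing, slopes, landmarks and the four
slope indicators."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icgperf import (AnalysisConfig, KineticParams, SmoothingConfig,
                     analyze_curve, compute_egress, compute_ingress,
                     compute_max_egress, compute_max_ingress,
                     detect_ingress_begin, locate_maximum_intensity,
                     slope_series, smooth_curve)
from icgperf.io import BackgroundStats, PerfusionCurve

from conftest import dense_grid_features, make_curve


def curve_from(t, y, roi_id=1, location="body"):
    return PerfusionCurve(roi_id=roi_id, location=location,
                          t=np.asarray(t, float), intensity=np.asarray(y, float))


def zero_bg():
    return BackgroundStats(mean=0.0, sd=0.0, slope_sd=0.0, n_pixels=1)


class TestSmoothing:
    def test_constant_curve_unchanged(self):
        c = curve_from(np.arange(40) / 4.0, np.full(40, 3.5))
        out = smooth_curve(c)
        np.testing.assert_array_equal(out.smoothed, c.intensity)

    def test_linear_ramp_unchanged_in_interior(self):
        t = np.arange(40) / 4.0
        c = smooth_curve(curve_from(t, 2.0 * t))
        np.testing.assert_allclose(c.smoothed[3:-3], 2.0 * t[3:-3], rtol=1e-12)

    def test_smoothing_reduces_noise(self, std_params):
        from icgperf import gamma_variate_curve

        rng = np.random.default_rng(3)
        t = np.arange(480) / 4.0
        clean = np.asarray(gamma_variate_curve(std_params, t))
        noisy = clean + rng.normal(size=t.size)
        c = smooth_curve(curve_from(t, noisy))
        assert np.mean((c.smoothed - clean) ** 2) < np.mean((noisy - clean) ** 2)

    def test_window_longer_than_recording_rejected(self):
        c = curve_from([0.0, 0.25, 0.5], [1, 2, 3])
        with pytest.raises(ValueError, match="window"):
            smooth_curve(c, SmoothingConfig(window_s=10.0))


class TestSlopeSeries:
    def test_ramp_slope_exact(self):
        t = np.arange(40) / 4.0
        c = smooth_curve(curve_from(t, 2.0 * t))
        s = slope_series(c)
        np.testing.assert_allclose(s[3:-3], 2.0, rtol=1e-12)

    def test_constant_gives_zeros(self):
        c = smooth_curve(curve_from(np.arange(20) / 4.0, np.full(20, 9.0)))
        np.testing.assert_array_equal(slope_series(c), np.zeros(20))

    def test_requires_smoothing_first(self):
        with pytest.raises(ValueError, match="smooth"):
            slope_series(curve_from(np.arange(10.0), np.arange(10.0)))


class TestIngressBegin:
    def test_ramp_onset_detected_at_first_sample_of_run(self):
        # flat baseline, then a ramp far above threshold starting at t = 20
        t = np.arange(200) / 4.0
        thr_slope = 1.0
        y = np.where(t <= 20.0, 0.0, (t - 20.0) * 10 * thr_slope)
        bg = BackgroundStats(mean=0.0, sd=0.0, slope_sd=thr_slope / 3.0, n_pixels=1)
        c = smooth_curve(curve_from(t, y))
        t_begin, ok = detect_ingress_begin(c, bg)
        assert ok
        assert 20.0 <= t_begin <= 20.0 + 2 / 4.0
        # independent scan oracle over the same raw slope series
        s = np.gradient(y, t)
        s_central = np.empty_like(y)
        s_central[1:-1] = (y[2:] - y[:-2]) / (t[2:] - t[:-2])
        s_central[0] = (y[1] - y[0]) / (t[1] - t[0])
        s_central[-1] = (y[-1] - y[-2]) / (t[-1] - t[-2])
        above = s_central > thr_slope
        runs = [i for i in range(len(above) - 2) if above[i:i + 3].all()]
        assert t_begin == t[runs[0]]

    def test_ramp_from_start_detected_at_first_sample(self):
        t = np.arange(40) / 4.0
        c = smooth_curve(curve_from(t, 5.0 * t))
        t_begin, ok = detect_ingress_begin(c, zero_bg())
        assert ok and t_begin == 0.0

    def test_pure_noise_control_not_detected(self):
        rng = np.random.default_rng(1)
        t = np.arange(480) / 4.0
        y = 5.0 + rng.normal(size=t.size) * 0.5
        c = smooth_curve(curve_from(t, y, location="control"))
        sd = np.std(np.gradient(y, t))
        bg = BackgroundStats(mean=5.0, sd=0.5, slope_sd=sd, n_pixels=1)
        _, ok = detect_ingress_begin(c, bg)
        assert not ok

    def test_constant_curve_not_detected(self):
        c = smooth_curve(curve_from(np.arange(40) / 4.0, np.full(40, 2.0)))
        _, ok = detect_ingress_begin(c, zero_bg())
        assert not ok


class TestMaximumIntensity:
    def test_unimodal_peak_location(self, std_params, quiet_bg):
        c = smooth_curve(make_curve(std_params))
        t_max, i_max = locate_maximum_intensity(c)
        assert abs(t_max - 18.0) <= 0.25
        assert i_max == pytest.approx(105.0, rel=0.01)

    def test_tie_broken_to_earliest(self):
        t = np.arange(200) / 4.0
        y = np.zeros(t.size)
        y[(t >= 28) & (t <= 31)] = 10.0  # plateau
        y[(t >= 38) & (t <= 41)] = 10.0  # equal later plateau
        c = curve_from(t, y)
        c = replace(c, smoothed=y)  # bypass smoothing to keep exact ties
        t_max, _ = locate_maximum_intensity(c)
        assert t_max == 28.0

    def test_monotone_curve_peaks_at_last_sample(self):
        t = np.arange(40) / 4.0
        c = smooth_curve(curve_from(t, t * 3.0))
        t_max, _ = locate_maximum_intensity(c)
        assert t_max == t[-1]


class TestIndicators:
    def test_ingress_secant_arithmetic(self):
        # I(10 s) = 10, I(30 s) = 110 -> 5 i/s
        t = np.arange(200) / 4.0
        y = np.interp(t, [0, 10, 30, 49.75], [10, 10, 110, 110])
        c = replace(curve_from(t, y), smoothed=y)
        val, ok = compute_ingress(c, 10.0, 30.0)
        assert ok and val == pytest.approx(5.0)

    def test_ramp_ingress_equals_slope(self):
        t = np.arange(80) / 4.0
        c = smooth_curve(curve_from(t, 3.0 * t))
        # exact on an interior window where the moving average is affine-exact
        val, ok = compute_ingress(c, 1.0, 15.0)
        assert ok and val == pytest.approx(3.0, rel=1e-12)
        mx, ok = compute_max_ingress(c, 1.0, 15.0)
        assert ok and mx == pytest.approx(3.0, rel=1e-12)
        # full range: only the shrinking edge windows deviate slightly
        val, ok = compute_ingress(c, 0.0, float(t[-1]))
        assert ok and val == pytest.approx(3.0, rel=0.03)

    def test_degenerate_phase_invalid(self):
        t = np.arange(40) / 4.0
        c = smooth_curve(curve_from(t, t))
        _, ok = compute_ingress(c, 5.0, 5.0)
        assert not ok

    def test_egress_formula_arithmetic(self):
        # I_tmax = 200, I(t_max + 5) = 180 -> -4 i/s
        t = np.arange(200) / 4.0
        y = np.interp(t, [0, 20, 25, 49.75], [200, 200, 180, 160])
        c = replace(curve_from(t, y), smoothed=y)
        egress, _, ok = compute_egress(c, 20.0)
        assert ok and egress == pytest.approx(-4.0)

    def test_plateau_after_peak_gives_zero_egress(self):
        t = np.arange(200) / 4.0
        y = np.interp(t, [0, 10, 20, 49.75], [0, 0, 100, 100])
        c = replace(curve_from(t, y), smoothed=y)
        egress, _, ok = compute_egress(c, 30.0)
        assert ok and egress == 0.0

    def test_egress_invalid_near_recording_end(self):
        t = np.arange(40) / 4.0
        y = t.copy()
        c = replace(curve_from(t, y), smoothed=y)
        _, _, ok = compute_egress(c, float(t[-1]) - 2.0)
        assert not ok

    def test_linear_decay_max_egress(self):
        t = np.arange(200) / 4.0
        y = np.interp(t, [0, 10, 20, 49.75], [0, 0, 100, -19.0])
        c = smooth_curve(curve_from(t, y))
        val, ok = compute_max_egress(c, 20.0)
        assert ok and val == pytest.approx(-4.0, rel=1e-6)

    def test_monotone_rise_has_no_egress_phase(self):
        t = np.arange(40) / 4.0
        c = smooth_curve(curve_from(t, t))
        _, ok = compute_max_egress(c, float(t[-1]))
        assert not ok


class TestAnalyzeCurve:
    def test_noiseless_curve_recovers_ground_truth(self, std_params, quiet_bg):
        feats = analyze_curve(make_curve(std_params), quiet_bg)
        oracle = dense_grid_features(std_params)
        for name in ("ingress", "max_ingress", "egress", "max_egress",
                     "t_max", "i_max"):
            assert getattr(feats, name) == pytest.approx(oracle[name], rel=0.05), name
        assert all(feats.valid.values())

    def test_constant_curve_all_slope_features_invalid(self, quiet_bg):
        c = curve_from(np.arange(40) / 4.0, np.full(40, 8.0))
        feats = analyze_curve(c, quiet_bg)
        assert not feats.valid["t_ingress_begin"]
        for name in ("ingress", "max_ingress", "egress", "max_egress"):
            assert not feats.valid[name]
            assert np.isnan(getattr(feats, name))
        assert any("no perfusion signal" in n for n in feats.notes)

    def test_control_roi_flagged_not_raised(self):
        rng = np.random.default_rng(9)
        t = np.arange(480) / 4.0
        y = 5.0 + 0.5 * rng.normal(size=t.size)
        c = curve_from(t, y, location="control")
        sd = float(np.std(np.diff(y) * 4.0))
        bg = BackgroundStats(mean=5.0, sd=0.5, slope_sd=sd / np.sqrt(2), n_pixels=1)
        feats = analyze_curve(c, bg)
        assert not feats.valid["ingress"]
        assert any("no perfusion signal" in n for n in feats.notes)

    def test_max_ingress_at_least_mean_ingress(self, quiet_bg):
        rng = np.random.default_rng(5)
        for _ in range(10):
            p = KineticParams(baseline=rng.uniform(2, 10),
                              amplitude=rng.uniform(40, 150),
                              t_arrival=rng.uniform(5, 20),
                              time_to_peak=rng.uniform(6, 15),
                              shape=rng.uniform(1.2, 3.5))
            feats = analyze_curve(make_curve(p), quiet_bg)
            assert feats.valid["ingress"] and feats.valid["max_ingress"]
            assert feats.max_ingress >= feats.ingress > 0


class TestEquivariances:
    """Offset invariance, scale equivariance, time-shift equivariance."""

    SLOPES = ("ingress", "max_ingress", "egress", "max_egress")

    @staticmethod
    def _features(params, quiet_bg, offset=0.0, scale=1.0):
        base = make_curve(params)
        y = scale * base.intensity + offset
        bg = BackgroundStats(mean=scale * quiet_bg.mean + offset, sd=0.0,
                             slope_sd=0.0, n_pixels=quiet_bg.n_pixels)
        return analyze_curve(replace(base, intensity=y), bg)

    @given(offset=st.floats(0.0, 500.0))
    @settings(max_examples=20, deadline=None)
    def test_offset_invariance(self, offset):
        quiet = BackgroundStats(5.0, 0.0, 0.0, 25)
        p = KineticParams(5.0, 100.0, 10.0, 8.0, 2.0, 0.0)
        f0 = self._features(p, quiet)
        f1 = self._features(p, quiet, offset=offset)
        for name in self.SLOPES:
            assert getattr(f1, name) == pytest.approx(getattr(f0, name), rel=1e-6)
        assert f1.t_max == f0.t_max
        assert f1.i_max == pytest.approx(f0.i_max + offset)

    @given(scale=st.floats(0.01, 100.0))
    @settings(max_examples=20, deadline=None)
    def test_scale_equivariance(self, scale):
        quiet = BackgroundStats(5.0, 0.0, 0.0, 25)
        p = KineticParams(5.0, 100.0, 10.0, 8.0, 2.0, 0.0)
        f0 = self._features(p, quiet)
        f1 = self._features(p, quiet, scale=scale)
        for name in self.SLOPES:
            assert getattr(f1, name) == pytest.approx(scale * getattr(f0, name),
                                                      rel=1e-6)
        assert f1.t_ingress_begin == f0.t_ingress_begin
        assert f1.t_max == f0.t_max

    @pytest.mark.parametrize("delta", [0.25, 2.0, 7.5])
    def test_time_shift_equivariance(self, delta, quiet_bg):
        p0 = KineticParams(5.0, 100.0, 10.0, 8.0, 2.0, 0.0)
        p1 = replace(p0, t_arrival=10.0 + delta)
        f0 = analyze_curve(make_curve(p0), quiet_bg)
        f1 = analyze_curve(make_curve(p1), quiet_bg)
        assert f1.t_ingress_begin == pytest.approx(f0.t_ingress_begin + delta)
        assert f1.t_max == pytest.approx(f0.t_max + delta)
        for name in self.SLOPES:
            assert getattr(f1, name) == pytest.approx(getattr(f0, name), rel=1e-3)
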