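"""Trace normalisation, ratios, recoil velocimetry, lag, orientation."""

import numpy as np
import pytest

from vesselmech.image_quant import (
    IntensityTrace,
    JunctionCortexMeasurement,
    background_subtract,
    classify_orientation,
    combine_views,
    crosscorr_lag,
    log_minmax_normalize,
    junction_cortex_ratio,
    recoil_from_rois,
    recoil_velocity,
    trace_gap_edges,
)
from vesselmech.synthetic import (
    KymographSpec,
    LaggedSeriesSpec,
    TextureSpec,
    gen_kymograph,
    gen_lagged_series,
    gen_texture_panel,
)


def trace(values, dt=1.0):
    values = np.asarray(values, float)
    return IntensityTrace(np.arange(values.size) * dt, values)


class TestNormalization:
    def test_background_subtract(self):
        out = background_subtract(trace([5.0, 6.0]), 5.0)
        assert np.allclose(out.values, [0.0, 1.0])
        same = background_subtract(trace([5.0, 6.0]), 0.0)
        assert np.allclose(same.values, [5.0, 6.0])

    def test_log_linear_sequence_maps_to_half(self):
        out = log_minmax_normalize(trace([1.0, 10.0, 100.0]))
        assert np.allclose(out.values, [0.0, 0.5, 1.0])

    def test_bounds_attained(self):
        rng = np.random.default_rng(0)
        out = log_minmax_normalize(trace(rng.uniform(0.5, 9.0, 50)))
        assert out.values.min() == 0.0
        assert out.values.max() == 1.0

    def test_direct_arithmetic_example(self):
        out = log_minmax_normalize(trace([1.0, 2.0, 3.0]))
        assert out.values[1] == pytest.approx(np.log10(2) / np.log10(3))

    def test_scale_invariance_above_floor(self):
        v = np.array([1.0, 3.0, 7.0, 2.0])
        a = log_minmax_normalize(trace(v)).values
        b = log_minmax_normalize(trace(13.7 * v)).values
        assert np.allclose(a, b)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="dynamic range"):
            log_minmax_normalize(trace([2.0, 2.0, 2.0]))

    def test_negative_values_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipping"):
            out = log_minmax_normalize(trace([-1.0, 5.0, 50.0]))
        assert np.all(np.isfinite(out.values))


class TestJunctionCortexRatio:
    def test_log10_of_ten(self):
        m = JunctionCortexMeasurement(np.full(6, 20.0), np.full(10, 2.0),
                                      np.zeros(2))
        assert junction_cortex_ratio(m) == pytest.approx(1.0)

    def test_equal_means_give_zero(self):
        m = JunctionCortexMeasurement(np.full(6, 7.0), np.full(10, 7.0),
                                      np.zeros(2))
        assert junction_cortex_ratio(m) == pytest.approx(0.0)

    def test_background_subtraction_arithmetic(self):
        m = JunctionCortexMeasurement(np.full(6, 21.0), np.full(10, 3.0),
                                      np.full(2, 1.0))
        assert junction_cortex_ratio(m) == pytest.approx(1.0)

    def test_gain_invariance(self):
        j, c, b = np.full(6, 30.0), np.full(10, 6.0), np.full(2, 2.0)
        r1 = junction_cortex_ratio(JunctionCortexMeasurement(j, c, b))
        r2 = junction_cortex_ratio(JunctionCortexMeasurement(5 * j, 5 * c, 5 * b))
        assert r1 == pytest.approx(r2)

    def test_signal_below_background(self):
        m = JunctionCortexMeasurement(np.full(6, 1.0), np.full(10, 5.0),
                                      np.full(2, 2.0))
        with pytest.raises(ValueError, match="below background"):
            junction_cortex_ratio(m)


class TestRecoil:
    def test_noiseless_kymograph_gap_series_matches_truth(self):
        spec = KymographSpec(true_velocity=0.4, noise_sd=0.0, edge_blur=0.1)
        kym, truth = gen_kymograph(spec)
        gaps = trace_gap_edges(kym)
        valid = np.isfinite(truth)
        assert np.all(np.isnan(gaps[: spec.n_pre_frames]))
        assert np.allclose(gaps[valid], truth[valid], atol=0.5 * spec.pixel_size)

    def test_intensity_rescaling_leaves_gaps_unchanged(self):
        from vesselmech.image_quant import Kymograph

        kym, _ = gen_kymograph(KymographSpec(noise_sd=0.0))
        g1 = trace_gap_edges(kym)
        kym2 = Kymograph(kym.matrix * 4.2 + 0.0, kym.pixel_size,
                         kym.frame_interval, kym.ablation_frame)
        g2 = trace_gap_edges(kym2)
        assert np.allclose(g1[np.isfinite(g1)], g2[np.isfinite(g2)])

    def test_velocity_formula(self):
        t = np.arange(0, 10.25, 0.25)
        gaps = 0.6 + 0.4 * t
        v, slope = recoil_velocity(t, gaps)
        assert v == pytest.approx(0.4)
        assert slope == pytest.approx(0.4)
        v0, _ = recoil_velocity(t, np.full_like(t, 0.6))
        assert v0 == 0.0

    def test_noisy_recovery_and_least_squares_crosscheck(self):
        spec = KymographSpec(true_velocity=0.5, noise_sd=0.05, edge_blur=0.15,
                             seed=11, n_frames=50)
        kym, _ = gen_kymograph(spec)
        gaps = trace_gap_edges(kym)
        t = kym.times - kym.times[spec.n_pre_frames]
        v, slope = recoil_velocity(t, gaps, ablation_time=0.0, window=10.0)
        assert v == pytest.approx(0.5, abs=0.05)
        assert abs(v - slope) < 0.02

    def test_unbiased_over_seeds(self):
        vs = []
        for seed in range(50):
            spec = KymographSpec(true_velocity=0.5, noise_sd=0.05,
                                 edge_blur=0.15, seed=seed)
            kym, _ = gen_kymograph(spec)
            gaps = trace_gap_edges(kym)
            t = kym.times - kym.times[spec.n_pre_frames]
            vs.append(recoil_velocity(t, gaps)[0])
        assert np.mean(vs) == pytest.approx(0.5, abs=0.01)

    def test_three_roi_averaging(self):
        series = []
        for v in (0.3, 0.4, 0.5):
            t = np.arange(0, 10.5, 0.5)
            series.append((t, 0.6 + v * t))
        res = recoil_from_rois(series)
        assert res.per_roi_velocity == pytest.approx((0.3, 0.4, 0.5))
        assert res.mean_velocity == pytest.approx(0.4)
        assert res.window == 10.0

    def test_window_too_short(self):
        with pytest.raises(ValueError, match="window too short"):
            recoil_velocity(np.array([0.0, 20.0]), np.array([1.0, 2.0]),
                            window=10.0)


class TestCrossCorrLag:
    def test_integer_shift_exact(self):
        rng = np.random.default_rng(1)
        from scipy.ndimage import gaussian_filter1d

        a = gaussian_filter1d(rng.standard_normal(300), 4)
        b = np.roll(a, 5)
        lag, corr = crosscorr_lag(a[20:-20], b[20:-20], 0.25, max_lag=10.0)
        assert lag == pytest.approx(5 * 0.25, abs=0.125)
        assert corr > 0.99

    def test_anticorrelated_at_zero(self):
        rng = np.random.default_rng(2)
        a = np.sin(np.arange(200) / 7.0) + 0.01 * rng.standard_normal(200)
        lag, corr = crosscorr_lag(a, -a, 1.0, max_lag=20.0)
        assert abs(lag) < 0.5
        assert corr == pytest.approx(-1.0, abs=0.01)

    def test_generator_pair_negative_lag_recovery(self):
        spec = LaggedSeriesSpec(true_lag=2.5, correlation_sign="negative",
                                noise_sd=0.1, seed=4)
        t, a, b = gen_lagged_series(spec)
        lag, corr = crosscorr_lag(a, b, spec.frame_interval, max_lag=10.0,
                                  mode="negative")
        assert corr < 0
        assert lag == pytest.approx(2.5, abs=spec.frame_interval)

    def test_too_short_record(self):
        with pytest.raises(ValueError, match="insufficient"):
            crosscorr_lag(np.arange(10.0), np.arange(10.0), 1.0, max_lag=6.0)


class TestOrientationClassifier:
    def test_constructed_textures(self):
        for label in ("C", "M", "L"):
            img = TextureSpec(label=label, noise_sd=0.05, seed=1)
            from vesselmech.synthetic import gen_oriented_texture

            call = classify_orientation(gen_oriented_texture(img))
            assert call.label == label
            assert 0.0 <= call.coherence <= 1.0

    def test_panel_accuracy_at_least_90_percent(self):
        images, labels = gen_texture_panel(n_per_class=20, seed=0)
        calls = [classify_orientation(img).label for img in images]
        acc = np.mean([c == t for c, t in zip(calls, labels)])
        assert acc >= 0.9

    def test_flat_image_rejected(self):
        with pytest.raises(ValueError, match="no texture"):
            classify_orientation(np.ones((32, 32)))

    def test_combine_views_rules(self):
        assert combine_views("C", "C") == "C"
        assert combine_views("M", "C") == "C-M"
        assert combine_views("L", "M") == "M-L"
        assert combine_views("C", "L") == "C-L"
        with pytest.raises(ValueError):
            combine_views("C", "X")
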