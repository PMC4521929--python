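"""Estimators: CDFs with binomial bands, MSD, exponents, FD histograms."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mobosim.stats import (SummaryCurves, empirical_cdf, msd_curve,
                           anomaly_exponent, fd_histogram, cdf_difference,
                           histogram_modes, is_bimodal, Z99)


class TestEmpiricalCdf:
    def test_basic_fractions(self):
        c = empirical_cdf([1.0, 2.0, 3.0], [2.0])
        assert c.estimate[0] == pytest.approx(2.0 / 3.0)

    def test_halfwidth_at_half_matches_printed_value(self):
        # p-hat = 0.5, n = 10000: 2.56 sqrt(0.25/10000) = 0.0128 ~ 0.013
        samples = np.concatenate([np.zeros(5000), np.ones(5000)])
        c = empirical_cdf(samples, [0.5])
        assert c.estimate[0] == pytest.approx(0.5)
        assert c.halfwidth[0] == pytest.approx(0.0128, abs=1e-6)
        assert round(float(c.halfwidth[0]), 3) == 0.013

    def test_degenerate_p_gives_zero_halfwidth(self):
        c = empirical_cdf([1.0, 1.0], [0.0, 2.0])
        np.testing.assert_allclose(c.estimate, [0.0, 1.0])
        np.testing.assert_allclose(c.halfwidth, [0.0, 0.0])

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            empirical_cdf([], [0.0])

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=50),
           st.integers(5, 40))
    def test_monotone_and_bounded(self, samples, n_eval):
        ev = np.linspace(-11, 11, n_eval)
        c = empirical_cdf(samples, ev)
        assert np.all(np.diff(c.estimate) >= 0)
        assert np.all((c.estimate >= 0) & (c.estimate <= 1))
        assert np.all(c.halfwidth >= 0)
        # half-width maximal at p = 0.5 for fixed n
        assert c.halfwidth.max() <= Z99 * 0.5 / np.sqrt(c.n) + 1e-12


class TestMsdCurve:
    def test_stationary_replicates_have_zero_msd(self):
        c = msd_curve(np.zeros((10, 4)), [0.1, 0.2, 0.3, 0.4])
        np.testing.assert_allclose(c.estimate, 0.0)
        np.testing.assert_allclose(c.halfwidth, 0.0)

    def test_free_2d_diffusion_matches_4dt(self, rng):
        # closed-form oracle: MSD of free 2-D diffusion, D = 1, t = 1, is 4
        n = 10_000
        sq = np.sum(rng.normal(0.0, np.sqrt(2.0), size=(n, 2)) ** 2,
                    axis=1)[:, None]
        c = msd_curve(sq, [1.0])
        assert abs(c.estimate[0] - 4.0) < 3 * c.halfwidth[0] / Z99  # 3 SEM

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            msd_curve(np.zeros((1, 3)), [1, 2, 3])

    def test_pooled_equals_weighted_mean_of_batches(self, rng):
        sq = rng.exponential(1.0, size=(40, 3))
        pooled = msd_curve(sq, [1, 2, 3]).estimate
        b1 = msd_curve(sq[:25], [1, 2, 3]).estimate
        b2 = msd_curve(sq[25:], [1, 2, 3]).estimate
        np.testing.assert_allclose(pooled, (25 * b1 + 15 * b2) / 40)

    def test_sem_convention_scales_by_z(self, rng):
        sq = rng.exponential(1.0, size=(50, 2))
        ci = msd_curve(sq, [1, 2], convention="ci99")
        sem = msd_curve(sq, [1, 2], convention="sem")
        np.testing.assert_allclose(ci.halfwidth, Z99 * sem.halfwidth)


class TestAnomalyExponent:
    @pytest.mark.parametrize("alpha", [0.5, 1.0, 2.0])
    def test_recovers_noiseless_power_law(self, alpha):
        t = np.linspace(0.1, 5.0, 40)
        curve = SummaryCurves(t, 3.0 * t ** alpha, np.zeros_like(t), 100)
        est, _ = anomaly_exponent(curve)
        assert est == pytest.approx(alpha, abs=0.05)

    def test_window_restricts_fit(self):
        t = np.linspace(0.1, 10.0, 100)
        y = np.where(t < 2.0, 4.0 * t, 8.0 * (t / 2.0) ** 2)
        curve = SummaryCurves(t, y, np.zeros_like(t), 100)
        early, _ = anomaly_exponent(curve, window=(0.1, 1.9))
        late, _ = anomaly_exponent(curve, window=(2.5, 10.0))
        assert early == pytest.approx(1.0, abs=0.02)
        assert late == pytest.approx(2.0, abs=0.02)

    def test_too_few_points_rejected(self):
        curve = SummaryCurves([1.0, 2.0], [1.0, 2.0], [0, 0], 10)
        with pytest.raises(ValueError):
            anomaly_exponent(curve)


class TestFdHistogram:
    def test_width_follows_iqr_rule(self, rng):
        # direct quantile oracle on a uniform(0, 1) sample
        x = rng.random(10_000)
        edges, _ = fd_histogram(x)
        width = edges[1] - edges[0]
        q75, q25 = np.percentile(x, [75, 25])
        assert width == pytest.approx(2.0 * (q75 - q25) * 10_000 ** (-1 / 3),
                                      rel=1e-12)

    def test_width_scales_with_sample_size(self, rng):
        x = rng.standard_normal(500)
        w1 = np.diff(fd_histogram(x)[0])[0]
        w8 = np.diff(fd_histogram(np.tile(x, 8))[0])[0]
        assert w8 == pytest.approx(w1 / 2.0, rel=1e-9)  # 8^(-1/3) = 1/2

    def test_zero_iqr_falls_back_with_warning(self):
        with pytest.warns(UserWarning):
            edges, counts = fd_histogram(np.array([1.0] * 10 + [5.0]))
        assert counts.sum() == 11


class TestCdfDifference:
    def test_identical_curves_differ_by_zero(self):
        a = SummaryCurves([1, 2], [0.4, 0.6], [0, 0], 10)
        assert cdf_difference(a, a, 1.5) == 0.0

    def test_percentage_formula(self):
        a = SummaryCurves([1.0], [0.5], [0], 10)
        b = SummaryCurves([1.0], [0.45], [0], 10)
        assert cdf_difference(a, b, 1.0) == pytest.approx(10.0)

    def test_zero_reference_rejected(self):
        a = SummaryCurves([1.0], [0.0], [0], 10)
        with pytest.raises(ValueError):
            cdf_difference(a, a, 1.0)


class TestBimodality:
    def test_two_separated_peaks_detected(self):
        counts = np.array([1, 5, 30, 5, 1, 1, 1, 4, 25, 4, 1], dtype=float)
        peaks, _ = histogram_modes(counts)
        assert len(peaks) == 2
        assert is_bimodal(counts)

    def test_single_peak_not_bimodal(self, rng):
        x = rng.standard_normal(5000)
        _, counts = fd_histogram(x)
        assert not is_bimodal(counts)

    def test_shallow_trough_rejected(self):
        # two maxima whose trough stays above 80% of the smaller peak
        counts = np.array([10, 20, 19, 20, 10], dtype=float)
        assert not is_bimodal(counts, smooth=1)
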