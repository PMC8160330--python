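"""Interval statistics: MLE closed form, KS band, Fano factor and their oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ctcflow import (EventSeries, InsufficientDataError, SimConfig, compute_icis,
                     fano_factor, fit_exponential_mle, ks_exponential_band,
                     simulate_homogeneous_poisson)
from ctcflow.intervals import IntervalSet, fano_ci_95, ks_critical_value


def _interval_set(icis):
    icis = np.asarray(icis, dtype=float)
    return IntervalSet(icis=icis, n_events=icis.size + 1, duration_s=float(icis.sum()) + 1.0)


class TestComputeIcis:
    def test_regular_events(self):
        iv = compute_icis(EventSeries(np.array([0.0, 10.0, 20.0]), 30.0))
        assert np.array_equal(iv.icis, [10.0, 10.0])
        assert iv.mean_ici_s == 10.0

    def test_n_events_give_n_minus_one_intervals(self):
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0, 3000, 151))
        iv = compute_icis(EventSeries(t, 3000.0))
        assert iv.n_intervals == 150

    def test_single_event_is_insufficient(self):
        iv = compute_icis(EventSeries(np.array([5.0]), 10.0))
        assert iv.insufficient and iv.n_intervals == 0
        with pytest.raises(InsufficientDataError):
            fit_exponential_mle(iv)


class TestExponentialMle:
    @pytest.mark.parametrize("icis,expected", [([2.0] * 10, 0.5), ([1.0, 2.0, 3.0], 0.5)])
    def test_closed_form(self, icis, expected):
        fit = fit_exponential_mle(_interval_set(icis))
        assert fit.lambda_hat == pytest.approx(expected)

    def test_log_likelihood_value(self):
        iv = _interval_set([1.0, 2.0, 3.0])
        fit = fit_exponential_mle(iv)
        assert fit.log_likelihood == pytest.approx(3 * np.log(0.5) - 0.5 * 6.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-3, max_value=1e3), min_size=2, max_size=60),
           st.integers(min_value=0, max_value=10))
    def test_mle_matches_grid_search_maximizer(self, icis, _salt):
        """The closed form C/sum(ICI) maximizes C*log(lam) - lam*sum(ICI)."""
        iv = _interval_set(icis)
        fit = fit_exponential_mle(iv)
        c, total = iv.n_intervals, iv.icis.sum()
        grid = np.geomspace(fit.lambda_hat / 50, fit.lambda_hat * 50, 20001)
        ll = c * np.log(grid) - grid * total
        best = grid[np.argmax(ll)]
        assert best == pytest.approx(fit.lambda_hat, rel=5e-4)

    def test_all_zero_intervals_degenerate(self):
        with pytest.raises(InsufficientDataError):
            fit_exponential_mle(_interval_set([0.0, 0.0, 0.0]))


class TestKsBand:
    def test_asymptotic_critical_value(self):
        assert ks_critical_value(100) == pytest.approx(1.36 / 10.0)

    def test_exact_small_sample_quantile(self):
        # below n = 35 the exact Kolmogorov quantile replaces 1.36/sqrt(n)
        assert ks_critical_value(20) == pytest.approx(stats.kstwo.ppf(0.95, 20))
        assert ks_critical_value(20) != pytest.approx(1.36 / np.sqrt(20), rel=1e-3)

    def test_sample_at_model_quantiles_is_within_band(self):
        lam = 0.2
        n = 100
        q = (np.arange(1, n + 1)) / (n + 1)
        icis = -np.log(1 - q) / lam  # exact model quantiles
        iv = _interval_set(icis)
        res = ks_exponential_band(iv)
        assert res.within_band and res.d_max < res.d_crit_95

    def test_two_scale_mixture_mostly_rejected(self):
        rng = np.random.default_rng(7)
        rejected = 0
        n_rep = 200
        for _ in range(n_rep):
            scales = np.where(rng.uniform(size=150) < 0.9, 1.0, 50.0)
            iv = _interval_set(rng.exponential(scales))
            rejected += not ks_exponential_band(iv).within_band
        assert rejected / n_rep > 0.5

    def test_dmax_scale_equivariant_when_refit(self):
        rng = np.random.default_rng(3)
        icis = rng.exponential(20.0, 150)
        d1 = ks_exponential_band(_interval_set(icis)).d_max
        d2 = ks_exponential_band(_interval_set(icis * 1000.0)).d_max  # s -> ms
        assert d1 == pytest.approx(d2, rel=1e-12)

    def test_band_contains_empirical_iff_within(self, poisson_series):
        res = ks_exponential_band(compute_icis(poisson_series))
        m, e, lo, hi = res.band_curves.T
        assert res.within_band == bool(np.all((e >= lo) & (e <= hi)))


class TestFanoFactor:
    def test_constant_counts_zero_fano(self):
        t = np.concatenate([np.array([10.0, 30.0]) + 100 * k for k in range(6)])
        res = fano_factor(EventSeries(t, 600.0), 100.0)
        assert res.fano == 0.0

    def test_hand_arithmetic(self):
        # counts [0,2,0,2,0,2]: mean 1, sample variance 1.2
        t = np.concatenate([np.array([110.0, 130.0]) + 200 * k for k in range(3)])
        res = fano_factor(EventSeries(t, 600.0), 100.0)
        assert np.array_equal(res.counts, [0, 2, 0, 2, 0, 2])
        assert res.fano == pytest.approx(1.2)

    def test_ci_matches_chi2_quantiles(self):
        lo, hi = fano_ci_95(30)
        assert lo == pytest.approx(stats.chi2.ppf(0.025, 29) / 29)
        assert hi == pytest.approx(stats.chi2.ppf(0.975, 29) / 29)

    def test_partial_window_dropped(self):
        # 650-s session -> 6 full 100-s windows; event at 640 s is discarded
        t = np.array([50.0, 150.0, 250.0, 350.0, 450.0, 550.0, 640.0])
        res = fano_factor(EventSeries(t, 650.0), 100.0)
        assert res.counts.sum() == 6

    def test_too_few_windows_rejected(self):
        with pytest.raises(InsufficientDataError):
            fano_factor(EventSeries(np.array([1.0, 2.0]), 400.0), 100.0)

    def test_empty_session_rejected(self):
        with pytest.raises(InsufficientDataError):
            fano_factor(EventSeries(np.empty(0), 1000.0), 100.0)

    @pytest.mark.parametrize("window", [50.0, 100.0, 200.0])
    def test_poisson_calibration_across_windows(self, window):
        """Mean Fano ~ 1 for Poisson input at several window lengths."""
        fanos = []
        for seed in range(300):
            s = simulate_homogeneous_poisson(
                SimConfig(rate_per_s=0.05, session_length_s=3000, seed=seed))
            fanos.append(fano_factor(s, window).fano)
        assert np.mean(fanos) == pytest.approx(1.0, abs=0.07)


class TestPoissonCalibration:
    def test_fano_ci_coverage_near_nominal(self):
        inside = 0
        n_rep = 600
        for seed in range(n_rep):
            s = simulate_homogeneous_poisson(
                SimConfig(rate_per_s=0.05, session_length_s=3000, seed=1000 + seed))
            inside += fano_factor(s, 100.0).is_poisson_consistent
        assert inside / n_rep == pytest.approx(0.95, abs=0.03)

    def test_ks_band_is_conservative_under_null(self):
        """With lambda fit from the same data the unadjusted KS band contains
        the empirical CDF more often than the nominal 95% (Lilliefors effect)."""
        within = 0
        n_rep = 400
        for seed in range(n_rep):
            s = simulate_homogeneous_poisson(
                SimConfig(rate_per_s=0.05, session_length_s=3000, seed=2000 + seed))
            within += ks_exponential_band(compute_icis(s)).within_band
        assert within / n_rep >= 0.95
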