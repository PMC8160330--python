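"""Cosinor rhythmometry: exact recovery, grid-search oracle, group tests."""

import numpy as np
import pytest

from ctcflow import (InsufficientDataError, SimConfig, TimepointSeries, fit_cosinor,
                     peak_trough_fold_change, population_cosinor_compare,
                     series_from_sessions, simulate_circadian_cohort,
                     width_count_correlation)
from ctcflow.circadian import circular_mean_h, shorter_arc_h

ZT_GRID = np.array([1.25, 5.25, 9.25, 13.25, 17.25, 21.25])  # session midpoints


def _cosine_counts(zt, mesor, amp, acro):
    return mesor + amp * np.cos(2 * np.pi * (zt - acro) / 24.0)


class TestFitCosinor:
    def test_constant_counts_flat_fit(self):
        rng = np.random.default_rng(0)
        fit = fit_cosinor(TimepointSeries(ZT_GRID, 5.0 + rng.normal(0, 1e-9, ZT_GRID.size)))
        assert fit.amplitude == pytest.approx(0.0, abs=1e-6)
        assert fit.zero_amplitude_p > 0.5

    def test_noiseless_cosine_recovered_exactly(self):
        y = _cosine_counts(ZT_GRID, 5.0, 3.0, 13.0)
        fit = fit_cosinor(TimepointSeries(ZT_GRID, y))
        assert fit.mesor == pytest.approx(5.0, abs=1e-9)
        assert fit.amplitude == pytest.approx(3.0, abs=1e-9)
        assert fit.acrophase_h == pytest.approx(13.0, abs=1e-9)
        assert fit.zero_amplitude_p == pytest.approx(0.0, abs=1e-12)

    def test_fit_matches_dense_grid_search(self):
        rng = np.random.default_rng(1)
        y = np.clip(_cosine_counts(ZT_GRID, 10.0, 4.0, 7.0) + rng.normal(0, 1.0, ZT_GRID.size), 0, None)
        fit = fit_cosinor(TimepointSeries(ZT_GRID, y))

        # brute force over (mesor, amplitude, acrophase)
        mes = np.linspace(5, 15, 101)
        amp = np.linspace(0, 8, 81)
        acr = np.linspace(0, 24, 241, endpoint=False)
        best = (np.inf, None)
        for a in acr:
            basis = np.cos(2 * np.pi * (ZT_GRID - a) / 24.0)
            for A in amp:
                resid0 = y - A * basis
                for M in mes:
                    sse = np.sum((resid0 - M) ** 2)
                    if sse < best[0]:
                        best = (sse, (M, A, a))
        M, A, a = best[1]
        assert fit.mesor == pytest.approx(M, abs=0.1)
        assert fit.amplitude == pytest.approx(A, abs=0.15)
        assert shorter_arc_h(fit.acrophase_h, a) == pytest.approx(0.0, abs=0.15)

    def test_time_shift_equivariance(self):
        rng = np.random.default_rng(2)
        y = np.clip(_cosine_counts(ZT_GRID, 8.0, 3.0, 13.0) + rng.normal(0, 0.5, ZT_GRID.size), 0, None)
        f0 = fit_cosinor(TimepointSeries(ZT_GRID, y))
        f5 = fit_cosinor(TimepointSeries((ZT_GRID + 5.0) % 24.0, y))
        assert shorter_arc_h(f0.acrophase_h, f5.acrophase_h) == pytest.approx(5.0, abs=1e-6)
        assert f5.mesor == pytest.approx(f0.mesor, abs=1e-9)
        assert f5.amplitude == pytest.approx(f0.amplitude, abs=1e-9)
        assert f5.zero_amplitude_p == pytest.approx(f0.zero_amplitude_p, rel=1e-6)

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_cosinor(TimepointSeries(np.array([1.0, 5.0, 9.0]), np.array([1.0, 2.0, 3.0])))

    def test_zero_amplitude_test_is_calibrated(self):
        """Under flat counts with Poisson noise the rejection rate at
        alpha = 0.05 stays near 5%."""
        rng = np.random.default_rng(3)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            y = rng.poisson(50, ZT_GRID.size).astype(float)
            fit = fit_cosinor(TimepointSeries(ZT_GRID, y))
            rejections += fit.zero_amplitude_p < 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.02)


class TestAcrophaseRecovery:
    def test_cohort_recovers_acrophase_13(self, circadian_params):
        """Simulated reference design (8 mice, 30-min sessions ZT1..ZT21,
        rate peaking at ZT13) recovers the generating acrophase within 1 h."""
        cohort = simulate_circadian_cohort(
            SimConfig(seed=100, circadian_params=circadian_params), n_mice=8)
        acros, amps, mesors = [], [], []
        for sessions in cohort:
            fit = fit_cosinor(series_from_sessions(sessions))
            acros.append(fit.acrophase_h)
            amps.append(fit.amplitude)
            mesors.append(fit.mesor)
        assert shorter_arc_h(circular_mean_h(acros), 13.0) == pytest.approx(0.0, abs=1.0)
        # per-30-min counts: mesor 0.04*1800 = 72, amplitude 0.03*1800 = 54
        assert np.mean(mesors) == pytest.approx(72.0, rel=0.15)
        assert np.mean(amps) == pytest.approx(54.0, rel=0.15)


def _fits_for_shift(shift_h, seed, n_mice=8):
    from ctcflow.simulate import CircadianParams
    cp = CircadianParams(mesor_rate=0.04, amplitude_rate=0.03,
                         acrophase_h=(13.0 + shift_h) % 24.0)
    cohort = simulate_circadian_cohort(SimConfig(seed=seed, circadian_params=cp), n_mice)
    return [fit_cosinor(series_from_sessions(s)) for s in cohort]


class TestPopulationCompare:
    def test_identical_groups_not_significant(self):
        fits = _fits_for_shift(0.0, seed=10)
        for param in ("amplitude", "mesor", "acrophase"):
            res = population_cosinor_compare(fits, fits, param)
            assert res.p_value > 0.99
            assert res.difference == pytest.approx(0.0, abs=1e-9)

    def test_light_inversion_flips_acrophase_12h(self):
        """A 12-h phase-flipped group (dark-light inversion) shows a
        significant acrophase difference of ~12 h and unchanged amplitude/MESOR."""
        ld = _fits_for_shift(0.0, seed=20)
        dl = _fits_for_shift(12.0, seed=21)
        res = population_cosinor_compare(ld, dl, "acrophase")
        assert abs(res.difference) == pytest.approx(12.0, abs=1.0)
        assert res.p_value < 0.001
        for param in ("amplitude", "mesor"):
            assert population_cosinor_compare(ld, dl, param).p_value > 0.05

    def test_long_photoperiod_shifts_acrophase_4h(self):
        ld = _fits_for_shift(0.0, seed=30)
        ld168 = _fits_for_shift(4.0, seed=31)
        res = population_cosinor_compare(ld, ld168, "acrophase")
        assert res.difference == pytest.approx(4.0, abs=1.0)
        assert res.p_value < 0.01


class TestFoldChange:
    def test_flat_series_fold_change_one(self):
        group = [TimepointSeries(ZT_GRID, np.full(ZT_GRID.size, 7.0)) for _ in range(3)]
        # flat counts cannot anchor a peak; supply an external fit
        ref = fit_cosinor(TimepointSeries(ZT_GRID, _cosine_counts(ZT_GRID, 7.0, 2.0, 13.0)))
        res = peak_trough_fold_change(group, fit=ref)
        assert res.fold_change == pytest.approx(1.0)

    def test_closed_form_fold_change(self):
        """Counts from mesor 10, amplitude 6 give a peak:trough ratio near
        (10+6)/(10-6) = 4."""
        rng = np.random.default_rng(4)
        group = [
            TimepointSeries(ZT_GRID, np.clip(
                rng.poisson(np.clip(_cosine_counts(ZT_GRID, 10.0, 6.0, 13.0), 0.01, None) * 10) / 10.0,
                0, None))
            for _ in range(8)
        ]
        res = peak_trough_fold_change(group)
        expected = (10.0 + 6.0) / (10.0 - 6.0)
        # sessions sit at ZT13.25/ZT1.25, slightly off the true extrema
        assert res.fold_change == pytest.approx(expected, rel=0.25)
        assert res.p_value < 0.01


class TestWidthCountCorrelation:
    def test_perfect_positive(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = width_count_correlation(x, 2 * x)
        assert res.r == pytest.approx(1.0)
        assert res.p_value < 1e-6

    def test_perfect_negative(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert width_count_correlation(x, -x).r == pytest.approx(-1.0)

    def test_null_p_values_uniform(self):
        """Independent widths and counts give ~5% rejections at alpha=0.05
        (and adjusted R^2 may legitimately go negative)."""
        rng = np.random.default_rng(5)
        n_rep, rej, neg_adj = 500, 0, 0
        for _ in range(n_rep):
            res = width_count_correlation(rng.normal(size=6), rng.normal(size=6))
            rej += res.p_value < 0.05
            neg_adj += res.adjusted_r_squared < 0
        assert rej / n_rep == pytest.approx(0.05, abs=0.03)
        assert neg_adj > 0

    def test_zero_variance_rejected(self):
        with pytest.raises(InsufficientDataError):
            width_count_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
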