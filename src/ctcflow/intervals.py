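"""Poisson-process tests on inter-CTC intervals (ICIs).

A homogeneous Poisson stream has i.i.d. exponential inter-event intervals.
Two complementary checks are implemented:

* the exponential goodness-of-fit check — maximum-likelihood fit of the
  exponential intensity to the observed ICIs, then a Kolmogorov–Smirnov
  band around the fitted CDF: the model is accepted when the empirical CDF
  stays entirely inside the 95% band;
* the Fano factor of windowed counts — variance/mean of event counts in
  fixed windows, compared against the chi-squared confidence interval that
  the Fano factor of a Poisson stream satisfies ((N-1)*FF ~ chi2_{N-1}).

The KS band is built around the CDF fitted to the same intervals, which is
what practitioners plot; parameter estimation makes the unadjusted band
conservative (it contains the empirical CDF more often than the nominal
95%). This behaviour is intentional and documented rather than corrected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import stats

from .events import EventSeries, InsufficientDataError

#: Asymptotic two-sided Kolmogorov 95% constant: d_crit = 1.36 / sqrt(C).
KS_ASYMPTOTIC_C95 = 1.36
#: Below this interval count the exact Kolmogorov quantile replaces 1.36/sqrt(C).
KS_EXACT_MAX_N = 35


@dataclass
class IntervalSet:
    """Inter-event intervals of one session."""

    icis: np.ndarray
    n_events: int
    duration_s: float

    @property
    def n_intervals(self) -> int:
        return int(self.icis.size)

    @property
    def mean_ici_s(self) -> float:
        if self.icis.size == 0:
            return float("nan")
        return float(self.icis.mean())

    @property
    def insufficient(self) -> bool:
        return self.icis.size < 1


@dataclass
class ExponentialFit:
    """Closed-form MLE of the exponential intensity for a set of intervals."""

    lambda_hat: float
    log_likelihood: float
    n_intervals: int


@dataclass
class KSBandResult:
    d_max: float
    d_crit_95: float
    within_band: bool
    #: columns: model CDF (x of the KS plot), empirical CDF, lower band, upper band
    band_curves: np.ndarray


@dataclass
class FanoResult:
    window_length_s: float
    counts: np.ndarray
    fano: float
    ci_95: Tuple[float, float]

    @property
    def is_poisson_consistent(self) -> bool:
        return self.ci_95[0] <= self.fano <= self.ci_95[1]


def compute_icis(events: EventSeries) -> IntervalSet:
    """Differences between successive event times; n events give n-1 intervals.

    Sessions with fewer than two events yield an empty, ``insufficient``
    IntervalSet that downstream tests refuse.
    """
    icis = np.diff(events.timestamps)
    return IntervalSet(icis=icis, n_events=events.n_events, duration_s=events.duration_s)


def fit_exponential_mle(intervals: IntervalSet) -> ExponentialFit:
    """Maximize ``L(lambda) = C log(lambda) - lambda * sum(ICI)``; the
    maximizer is ``lambda_hat = C / sum(ICI)`` in closed form."""
    if intervals.n_intervals < 2:
        raise InsufficientDataError("need at least 2 intervals to fit")
    total = float(intervals.icis.sum())
    if total <= 0:
        raise InsufficientDataError("all intervals are zero; exponential fit is degenerate")
    c = intervals.n_intervals
    lam = c / total
    return ExponentialFit(
        lambda_hat=lam,
        log_likelihood=c * np.log(lam) - lam * total,
        n_intervals=c,
    )


def ks_critical_value(n: int, alpha: float = 0.05) -> float:
    """95% half-width of the KS band: exact Kolmogorov quantile for small n,
    asymptotic ``1.36/sqrt(n)`` otherwise."""
    if n < KS_EXACT_MAX_N:
        return float(stats.kstwo.ppf(1.0 - alpha, n))
    return KS_ASYMPTOTIC_C95 / np.sqrt(n)


def ks_exponential_band(intervals: IntervalSet, fit: Optional[ExponentialFit] = None,
                        alpha: float = 0.05) -> KSBandResult:
    """KS comparison of the empirical ICI CDF against the fitted exponential.

    ``band_curves`` is in KS-plot coordinates: the fitted model CDF on the
    x axis, the empirical CDF on y, and the 95% band as y = x +/- d_crit.
    ``within_band`` is equivalent to ``d_max < d_crit_95``.
    """
    if intervals.n_intervals < 2:
        raise InsufficientDataError("need at least 2 intervals for the KS band")
    if fit is None:
        fit = fit_exponential_mle(intervals)
    x = np.sort(intervals.icis)
    n = x.size
    model = 1.0 - np.exp(-fit.lambda_hat * x)  # exponential CDF, x >= 0
    ecdf_hi = np.arange(1, n + 1) / n
    ecdf_lo = np.arange(0, n) / n
    d_max = float(np.max(np.maximum(ecdf_hi - model, model - ecdf_lo)))
    d_crit = ks_critical_value(n, alpha)
    band = np.column_stack([model, ecdf_hi, model - d_crit, model + d_crit])
    return KSBandResult(
        d_max=d_max,
        d_crit_95=d_crit,
        within_band=d_max < d_crit,
        band_curves=band,
    )


def fano_ci_95(n_windows: int) -> Tuple[float, float]:
    """Chi-squared CI for the Fano factor of Poisson counts over N windows:
    (N-1)*FF ~ chi2_{N-1}, so CI = [chi2_{0.025}, chi2_{0.975}] / (N-1)."""
    df = n_windows - 1
    lo, hi = stats.chi2.ppf([0.025, 0.975], df) / df
    return float(lo), float(hi)


def fano_factor(events: EventSeries, window_length_s: float = 100.0) -> FanoResult:
    """Variance-to-mean ratio of event counts in consecutive fixed windows.

    Only full windows are counted; a partial window at the end of the
    session is dropped. Requires at least 5 full windows and at least one
    event (the Fano factor is undefined at zero mean).
    """
    if window_length_s <= 0:
        raise ValueError("window_length_s must be positive")
    n_win = int(events.duration_s // window_length_s)
    if n_win < 5:
        raise InsufficientDataError(
            f"session holds only {n_win} full windows of {window_length_s} s; need >= 5"
        )
    edges = np.arange(n_win + 1) * window_length_s
    counts = np.histogram(events.timestamps[events.timestamps < edges[-1]], bins=edges)[0]
    mean = counts.mean()
    if mean == 0:
        raise InsufficientDataError("no events in any window; Fano factor undefined")
    fano = float(counts.var(ddof=1) / mean)
    return FanoResult(
        window_length_s=window_length_s,
        counts=counts,
        fano=fano,
        ci_95=fano_ci_95(n_win),
    )
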