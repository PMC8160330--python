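"""Single-component cosinor rhythmometry for per-session CTC counts.

The model is the classical fixed-period cosinor

    y(t) = MESOR + A * cos(2*pi*(t - phi) / P) + e,

fit by ordinary least squares on the linearised basis
``[1, cos(w t), sin(w t)]`` with the period P fixed at 24 h. The MESOR is
the rhythm-adjusted mean, A >= 0 the amplitude, and the acrophase phi the
zeitgeber time of the fitted maximum, reported on [0, 24). Rhythmicity is
the zero-amplitude F-test of the two rhythm coefficients against the
intercept-only model.

Group comparisons follow the population-mean cosinor idea: each animal
contributes one fitted parameter set; MESOR and amplitude are compared by
unpaired t-tests on the per-animal estimates, and acrophases — circular
quantities — by a Watson–Williams F-test, with the group difference
reported on the shorter arc of the 24-h circle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Literal, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .events import EventSeries, InsufficientDataError

DEFAULT_PERIOD_H = 24.0


@dataclass
class TimepointSeries:
    """Counts per timed session for one animal (normalised per 30 min)."""

    zt_h: np.ndarray
    counts: np.ndarray
    mouse_id: str = "m0"
    schedule_label: Optional[str] = None

    def __post_init__(self) -> None:
        self.zt_h = np.asarray(self.zt_h, dtype=float) % 24.0
        self.counts = np.asarray(self.counts, dtype=float)
        if self.zt_h.shape != self.counts.shape:
            raise ValueError("zt_h and counts must have the same length")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


@dataclass
class CosinorFit:
    mesor: float
    amplitude: float
    acrophase_h: float
    period_h: float
    zero_amplitude_p: float
    zero_amplitude_f: float
    residual_se: float
    n_points: int

    def predict(self, zt_h: np.ndarray | float) -> np.ndarray | float:
        return self.mesor + self.amplitude * np.cos(
            2.0 * np.pi * (np.asarray(zt_h, dtype=float) - self.acrophase_h) / self.period_h
        )


@dataclass
class GroupComparison:
    parameter: str
    statistic: float
    p_value: float
    difference: float  # b - a; acrophase difference on the shorter arc (hours)


def series_from_sessions(sessions: Sequence[EventSeries],
                         normalise_to_s: float = 1800.0) -> TimepointSeries:
    """Collapse one animal's timed sessions to (session midpoint ZT, count).

    Counts are normalised to events per ``normalise_to_s`` seconds (default
    one 30-min session) so sessions of different lengths are comparable.
    """
    if not sessions:
        raise InsufficientDataError("no sessions supplied")
    zt, counts = [], []
    for s in sessions:
        if s.zt_start_h is None:
            raise ValueError(f"session {s.session_id} has no zeitgeber start time")
        zt.append(s.zt_mid_h)
        counts.append(s.n_events * normalise_to_s / s.duration_s)
    return TimepointSeries(
        np.asarray(zt), np.asarray(counts),
        mouse_id=sessions[0].mouse_id, schedule_label=sessions[0].schedule_label,
    )


def fit_cosinor(series: TimepointSeries, period_h: float = DEFAULT_PERIOD_H) -> CosinorFit:
    """Least-squares single-component cosinor at fixed period."""
    t, y = series.zt_h, series.counts
    if np.unique(t).size < 4:
        raise InsufficientDataError("cosinor fit needs >= 4 distinct timepoints")
    w = 2.0 * np.pi / period_h
    X = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
    if np.linalg.matrix_rank(X) < 3:
        raise InsufficientDataError("rank-deficient cosinor design")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    m, bc, bs = beta
    amplitude = float(np.hypot(bc, bs))
    # y = m + bc cos(wt) + bs sin(wt) = m + A cos(w(t - phi)) with
    # bc = A cos(w phi), bs = A sin(w phi)
    acrophase = float((np.arctan2(bs, bc) / w) % period_h)

    resid = y - X @ beta
    sse1 = float(resid @ resid)
    sse0 = float(np.sum((y - y.mean()) ** 2))
    df1 = t.size - 3
    if df1 <= 0:
        raise InsufficientDataError("no residual degrees of freedom")
    if sse1 <= 0:  # perfect fit
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = ((sse0 - sse1) / 2.0) / (sse1 / df1)
        p = float(stats.f.sf(f_stat, 2, df1))
    return CosinorFit(
        mesor=float(m),
        amplitude=amplitude,
        acrophase_h=acrophase,
        period_h=period_h,
        zero_amplitude_p=p,
        zero_amplitude_f=float(f_stat),
        residual_se=float(np.sqrt(sse1 / df1)) if df1 > 0 else float("nan"),
        n_points=int(t.size),
    )


def circular_mean_h(hours: Sequence[float], period_h: float = DEFAULT_PERIOD_H) -> float:
    """Circular mean of clock times, on [0, period)."""
    ang = 2.0 * np.pi * np.asarray(hours, dtype=float) / period_h
    mean_ang = np.arctan2(np.mean(np.sin(ang)), np.mean(np.cos(ang)))
    return float((mean_ang * period_h / (2.0 * np.pi)) % period_h)


def shorter_arc_h(a: float, b: float, period_h: float = DEFAULT_PERIOD_H) -> float:
    """Signed difference b - a on the shorter arc, in (-period/2, period/2]."""
    d = (b - a) % period_h
    if d > period_h / 2.0:
        d -= period_h
    return float(d)


def _watson_williams(a_h: np.ndarray, b_h: np.ndarray,
                     period_h: float) -> Tuple[float, float]:
    """Watson–Williams two-sample test for equal circular means.

    Classical F approximation with the concentration correction factor;
    adequate for the moderately concentrated acrophase samples produced by
    per-animal cosinor fits.
    """
    ang = [2.0 * np.pi * np.asarray(x, dtype=float) / period_h for x in (a_h, b_h)]
    ns = np.array([len(x) for x in ang])
    n = ns.sum()
    rs = np.array([np.hypot(np.sum(np.sin(x)), np.sum(np.cos(x))) for x in ang])
    all_ang = np.concatenate(ang)
    r_all = np.hypot(np.sum(np.sin(all_ang)), np.sum(np.cos(all_ang)))
    rbar = rs.sum() / n
    # correction for the F approximation (Mardia & Jupp)
    kappa = _est_kappa(rbar)
    correction = 1.0 + 3.0 / (8.0 * kappa) if kappa > 0 else 1.0
    num = (n - 2) * (rs.sum() - r_all)
    den = n - rs.sum()
    if den <= 0:
        return float("inf"), 0.0
    f_stat = correction * num / den
    p = float(stats.f.sf(f_stat, 1, n - 2))
    return float(f_stat), p


def _est_kappa(rbar: float) -> float:
    """Approximate ML concentration of a von Mises sample from mean resultant length."""
    if rbar < 0.53:
        return 2 * rbar + rbar**3 + 5 * rbar**5 / 6
    if rbar < 0.85:
        return -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    return 1 / (rbar**3 - 4 * rbar**2 + 3 * rbar) if rbar < 1 else float("inf")


def population_cosinor_compare(
    group_a: Sequence[CosinorFit],
    group_b: Sequence[CosinorFit],
    parameter: Literal["amplitude", "mesor", "acrophase"],
) -> GroupComparison:
    """Compare one rhythm parameter between two groups of per-animal fits.

    MESOR and amplitude are compared by a two-sided unpaired t-test on the
    per-animal estimates. Acrophase is circular: fits with (numerically)
    zero amplitude carry no phase information and are excluded with a
    warning; remaining phases are tested with a Watson–Williams F-test and
    the difference of circular means is reported on the shorter arc.
    """
    if parameter not in ("amplitude", "mesor", "acrophase"):
        raise ValueError(f"unknown parameter {parameter!r}")
    if parameter in ("amplitude", "mesor"):
        a = np.array([getattr(f, parameter) for f in group_a], dtype=float)
        b = np.array([getattr(f, parameter) for f in group_b], dtype=float)
        if a.size < 3 or b.size < 3:
            raise InsufficientDataError("each group needs >= 3 fits")
        res = stats.ttest_ind(a, b)
        return GroupComparison(parameter, float(res.statistic), float(res.pvalue),
                               float(b.mean() - a.mean()))

    def usable(fits: Sequence[CosinorFit]) -> List[float]:
        kept = [f.acrophase_h for f in fits if f.amplitude > 1e-12]
        if len(kept) < len(fits):
            warnings.warn("excluded zero-amplitude fit(s) from acrophase comparison",
                          stacklevel=3)
        return kept

    a_h, b_h = usable(group_a), usable(group_b)
    if len(a_h) < 3 or len(b_h) < 3:
        raise InsufficientDataError("each group needs >= 3 usable acrophases")
    period = group_a[0].period_h
    f_stat, p = _watson_williams(np.asarray(a_h), np.asarray(b_h), period)
    diff = shorter_arc_h(circular_mean_h(a_h, period), circular_mean_h(b_h, period), period)
    return GroupComparison("acrophase", f_stat, p, diff)


@dataclass
class FoldChangeResult:
    fold_change: float
    peak_zt_h: float
    trough_zt_h: float
    peak_counts: np.ndarray
    trough_counts: np.ndarray
    t_statistic: float
    p_value: float

    @property
    def is_finite(self) -> bool:
        return np.isfinite(self.fold_change)


def peak_trough_fold_change(group: Sequence[TimepointSeries],
                            fit: Optional[CosinorFit] = None) -> FoldChangeResult:
    """Ratio of group mean counts at the sessions nearest the fitted peak
    and trough (acrophase and acrophase + 12 h), with an unpaired t-test
    between the per-animal peak and trough counts."""
    if not group:
        raise InsufficientDataError("empty group")
    if fit is None:
        pooled = TimepointSeries(
            np.concatenate([s.zt_h for s in group]),
            np.concatenate([s.counts for s in group]),
        )
        fit = fit_cosinor(pooled)
    period = fit.period_h
    trough_h = (fit.acrophase_h + period / 2.0) % period

    def nearest_counts(target_h: float) -> np.ndarray:
        vals = []
        for s in group:
            d = np.abs([shorter_arc_h(z, target_h, period) for z in s.zt_h])
            vals.append(s.counts[int(np.argmin(d))])
        return np.asarray(vals, dtype=float)

    peak_c = nearest_counts(fit.acrophase_h)
    trough_c = nearest_counts(trough_h)
    trough_mean = trough_c.mean()
    if trough_mean == 0:
        warnings.warn("zero mean trough count; fold change is infinite", stacklevel=2)
        fold = float("inf")
    else:
        fold = float(peak_c.mean() / trough_mean)
    if peak_c.size >= 2 and (peak_c.std() > 0 or trough_c.std() > 0):
        res = stats.ttest_ind(peak_c, trough_c)
        t_stat, p = float(res.statistic), float(res.pvalue)
    else:
        t_stat, p = float("nan"), float("nan")
    return FoldChangeResult(fold, fit.acrophase_h, trough_h, peak_c, trough_c, t_stat, p)


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    r_squared: float
    adjusted_r_squared: float
    n: int


def width_count_correlation(widths: Sequence[float], counts: Sequence[float]) -> CorrelationResult:
    """Pearson correlation between per-session mean peak widths and counts.

    Reports r, r^2 and the adjusted R^2 of the one-predictor linear fit
    separately (adjusted R^2 can be negative for null relationships; the
    three are easy to conflate in figure annotations).
    """
    x = np.asarray(widths, dtype=float)
    y = np.asarray(counts, dtype=float)
    if x.shape != y.shape:
        raise ValueError("widths and counts must be paired")
    if x.size < 3:
        raise InsufficientDataError("correlation needs n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise InsufficientDataError("zero variance; correlation undefined")
    r, p = stats.pearsonr(x, y)
    r2 = r * r
    n = x.size
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return CorrelationResult(float(r), float(p), float(r2), float(adj), int(n))
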