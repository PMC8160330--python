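"""PMT-like trace synthesis and spike detection.

A fluorescence in vivo flow cytometer records a photodetector voltage
trace; a cell crossing the excitation light sheet produces a roughly
Gaussian pulse above the baseline, and a cell cluster produces a signal
with several overlapping sub-peaks. This module synthesizes such traces
from an event stream (for verification) and detects spikes in them.

Detection pipeline:

1. baseline = running median of the trace (window much longer than a pulse);
2. noise sigma = 1.4826 * MAD of the baseline-subtracted trace;
3. contiguous regions above ``baseline + threshold_sigma * sigma`` are
   candidate signals;
4. within a region, local maxima separated by at least ``min_separation_ms``
   with prominence above the threshold count as sub-peaks; a region with
   two or more sub-peaks is one *cluster* detection (a cluster is counted
   as a single event at the global maximum of the region).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy import ndimage, signal

from .events import ConfigError, EventSeries

GAUSSIAN_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.355: FWHM = factor * sigma


@dataclass
class Trace:
    sample_rate_hz: float
    values: np.ndarray
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.sample_rate_hz <= 0:
            raise ConfigError("sample_rate_hz must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ConfigError("trace values must be finite")

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.values.size) / self.sample_rate_hz

    @property
    def duration_s(self) -> float:
        return self.values.size / self.sample_rate_hz


@dataclass
class DetectedPeak:
    t_s: float
    height: float
    width_ms: float
    n_subpeaks: int

    @property
    def is_cluster(self) -> bool:
        return self.n_subpeaks >= 2


@dataclass
class PeakShapeParams:
    """Gaussian pulse shape: amplitude and temporal sigma, with optional jitter."""

    amplitude: float = 10.0
    amplitude_cv: float = 0.0  # lognormal-ish amplitude spread (relative sd)
    sigma_ms: float = 1.0
    cluster_subpeak_range: tuple = (2, 4)  # sub-pulses per cluster event
    # sub-pulse gap as a fraction of FWHM; > 0.85 keeps the Gaussian sum
    # bimodal (two equal Gaussians merge below a 2-sigma separation), and
    # ~1.7 (4 sigma) leaves valleys deep enough that sub-peak prominence
    # clears a 5-sigma detection threshold at SNR 10
    cluster_gap_factor: float = 1.7


@dataclass
class NoiseParams:
    baseline: float = 0.0
    noise_sigma: float = 0.0


def synthesize_trace(events: EventSeries, shape: PeakShapeParams, noise: NoiseParams,
                     sample_rate_hz: float = 10_000.0, seed: int = 0,
                     duration_s: Optional[float] = None) -> Trace:
    """Render an event stream as a noisy trace of Gaussian pulses.

    Events flagged as clusters contribute 2–4 overlapping sub-pulses offset
    by sub-width gaps; all other events contribute a single pulse centred
    at their timestamp.
    """
    dur = duration_s if duration_s is not None else events.duration_s
    if events.n_events and events.timestamps[-1] >= dur:
        raise ConfigError("event beyond trace duration")
    rng = np.random.default_rng(seed)
    n = int(round(dur * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    values = np.full(n, noise.baseline, dtype=float)

    sigma_s = shape.sigma_ms / 1000.0
    fwhm_s = GAUSSIAN_FWHM_FACTOR * sigma_s
    flags = events.is_cluster if events.is_cluster is not None else np.zeros(events.n_events, bool)
    for t_ev, clustered in zip(events.timestamps, flags):
        if clustered:
            k = int(rng.integers(shape.cluster_subpeak_range[0],
                                 shape.cluster_subpeak_range[1] + 1))
            offsets = np.arange(k) * shape.cluster_gap_factor * fwhm_s
            offsets -= offsets.mean()
        else:
            offsets = np.array([0.0])
        for off in offsets:
            amp = shape.amplitude
            if shape.amplitude_cv > 0:
                amp *= rng.lognormal(0.0, shape.amplitude_cv)
            centre = t_ev + off
            lo = max(0, int((centre - 6 * sigma_s) * sample_rate_hz))
            hi = min(n, int((centre + 6 * sigma_s) * sample_rate_hz) + 1)
            values[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - centre) / sigma_s) ** 2)
    if noise.noise_sigma > 0:
        values += rng.normal(0.0, noise.noise_sigma, size=n)
    return Trace(sample_rate_hz=sample_rate_hz, values=values)


def _fwhm_ms(t: np.ndarray, y: np.ndarray, i_max: int) -> float:
    """Full width at half maximum of the excursion containing sample i_max,
    by linear interpolation on either side of the peak."""
    half = y[i_max] / 2.0
    i = i_max
    while i > 0 and y[i - 1] > half:
        i -= 1
    if i == 0:
        t_lo = t[0]
    else:
        frac = (y[i] - half) / (y[i] - y[i - 1])
        t_lo = t[i] - frac * (t[i] - t[i - 1])
    j = i_max
    while j < y.size - 1 and y[j + 1] > half:
        j += 1
    if j == y.size - 1:
        t_hi = t[-1]
    else:
        frac = (y[j] - half) / (y[j] - y[j + 1])
        t_hi = t[j] + frac * (t[j + 1] - t[j])
    return float((t_hi - t_lo) * 1000.0)


def detect_peaks(trace: Trace, threshold_sigma: float = 5.0,
                 min_separation_ms: float = 0.5,
                 baseline_window: int = 201,
                 noise_sigma: Optional[float] = None) -> List[DetectedPeak]:
    """Detect supra-threshold signals and classify single vs cluster.

    ``noise_sigma`` overrides the MAD estimate (useful for noiseless
    synthetic traces where the MAD of the residual is zero, in which case
    any excursion above the baseline is a signal).

    ``baseline_window`` (samples) must be much longer than the widest
    expected signal — more than twice the span of a multi-peak cluster —
    or the running median rides up onto the signal itself.
    """
    if threshold_sigma <= 0:
        raise ConfigError("threshold_sigma must be positive")
    if trace.values.size == 0:
        raise ConfigError("empty trace")
    y = trace.values
    baseline = ndimage.median_filter(y, size=baseline_window, mode="nearest")
    resid = y - baseline
    sigma = noise_sigma if noise_sigma is not None else float(
        1.4826 * np.median(np.abs(resid - np.median(resid)))
    )
    if sigma > 0:
        thresh = threshold_sigma * sigma
    else:
        # noiseless trace: any strictly positive excursion counts
        if resid.max() <= 0:
            return []
        thresh = 1e-9 * resid.max()

    above = resid > thresh
    if not above.any():
        return []
    # Hysteresis segmentation: a signal region is a contiguous run above
    # thresh/2 that contains at least one sample above thresh. This keeps
    # one noisy excursion from splitting into several detections.
    above_low = resid > thresh / 2.0
    idx = np.flatnonzero(above_low)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts_all = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends_all = np.concatenate((idx[breaks], [idx[-1]]))
    keep = [above[lo:hi + 1].any() for lo, hi in zip(starts_all, ends_all)]
    region_starts = starts_all[keep]
    region_ends = ends_all[keep]

    min_dist = max(1, int(round(min_separation_ms / 1000.0 * trace.sample_rate_hz)))
    t = trace.times_s
    peaks: List[DetectedPeak] = []
    for lo, hi in zip(region_starts, region_ends):
        seg = resid[lo:hi + 1]
        locs, _ = signal.find_peaks(seg, distance=min_dist, prominence=thresh)
        n_sub = max(1, int(locs.size))
        i_max = lo + int(np.argmax(seg))
        peaks.append(DetectedPeak(
            t_s=float(t[i_max]),
            height=float(resid[i_max]),
            width_ms=_fwhm_ms(t, resid, i_max),
            n_subpeaks=n_sub,
        ))
    return peaks


def peaks_to_events(peaks: Sequence[DetectedPeak], duration_s: float,
                    **series_kwargs) -> EventSeries:
    """Package detected peaks as an EventSeries (one timestamp per signal,
    clusters counted once)."""
    order = np.argsort([p.t_s for p in peaks])
    ps = [peaks[i] for i in order]
    return EventSeries(
        np.array([p.t_s for p in ps]),
        duration_s=duration_s,
        heights=np.array([p.height for p in ps]),
        widths_ms=np.array([p.width_ms for p in ps]),
        is_cluster=np.array([p.is_cluster for p in ps]),
        **series_kwargs,
    )


def peak_width_summary(peaks_by_session: dict) -> dict:
    """Per-session mean width and dispersion; empty sessions are excluded.

    ``peaks_by_session`` maps a session key (e.g. ZT hour) to a sequence of
    DetectedPeak. Returns {key: {"mean_width_ms", "sd_width_ms", "n"}}.
    """
    import warnings

    out = {}
    for key, peaks in peaks_by_session.items():
        widths = np.array([p.width_ms for p in peaks], dtype=float)
        if widths.size == 0:
            warnings.warn(f"session {key!r} has no peaks; excluded", stacklevel=2)
            continue
        out[key] = {
            "mean_width_ms": float(widths.mean()),
            "sd_width_ms": float(widths.std(ddof=1)) if widths.size > 1 else 0.0,
            "n": int(widths.size),
        }
    return out
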