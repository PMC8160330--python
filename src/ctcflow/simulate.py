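"""Synthetic CTC event-stream generators.

Three generating processes cover the regimes the downstream analyses
distinguish:

* a homogeneous Poisson process — the null model under which inter-event
  intervals are i.i.d. exponential and the Fano factor of windowed counts
  is 1;
* a Poisson cluster (Neyman–Scott) process — the bursty alternative in
  which cluster "parents" arrive as a homogeneous Poisson stream and each
  parent spawns a geometric number of events with exponential intra-cluster
  gaps, producing over-dispersed counts and non-exponential intervals;
* a 24-h cosine-modulated inhomogeneous Poisson process, sampled only
  inside scheduled detection sessions, emulating circadian modulation of
  the CTC release rate under a light-dark cycle.

All randomness flows from the seed carried in :class:`SimConfig`; a fixed
seed reproduces timestamps bit-exactly. Per-mouse streams are derived as
``seed + mouse_index`` so cohorts are reproducible member by member.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .events import ConfigError, EventSeries

#: The reference 24-h monitoring design: 30-min sessions every 4 h, ZT1–ZT21.
DEFAULT_SCHEDULE: Tuple[Tuple[float, float], ...] = tuple(
    (float(zt), 1800.0) for zt in (1, 5, 9, 13, 17, 21)
)


@dataclass
class BurstParams:
    """Poisson-cluster (Neyman–Scott) parameters.

    cluster_rate_per_s
        Arrival rate of cluster parents (homogeneous Poisson).
    mean_events_per_cluster
        Mean cluster size; sizes are geometric on {1, 2, ...} so every
        parent produces at least one event.
    intra_cluster_scale_s
        Mean gap (exponential scale) between successive events inside a
        cluster, in seconds.
    """

    cluster_rate_per_s: float
    mean_events_per_cluster: float
    intra_cluster_scale_s: float

    def validate(self) -> None:
        if self.cluster_rate_per_s <= 0:
            raise ConfigError("cluster_rate_per_s must be positive")
        if self.mean_events_per_cluster < 1:
            raise ConfigError("mean_events_per_cluster must be >= 1")
        if self.intra_cluster_scale_s <= 0:
            raise ConfigError("intra_cluster_scale_s must be positive")


@dataclass
class CircadianParams:
    """Cosine rate modulation: lambda(t) = mesor + amplitude*cos(2*pi*(t - acrophase)/period).

    Rates are in events/second; times on the zeitgeber clock in hours
    (ZT0 = lights-on). A modulated rate that would go negative is clipped
    at zero (with a warning at validation time).
    """

    mesor_rate: float
    amplitude_rate: float
    acrophase_h: float
    period_h: float = 24.0

    def validate(self) -> None:
        if self.mesor_rate < 0 or self.amplitude_rate < 0:
            raise ConfigError("mesor_rate and amplitude_rate must be non-negative")
        if self.period_h <= 0:
            raise ConfigError("period_h must be positive")
        if self.amplitude_rate > self.mesor_rate:
            warnings.warn(
                "amplitude_rate exceeds mesor_rate; the modulated rate will be "
                "clipped at zero around the trough",
                stacklevel=3,
            )

    def rate_at(self, zt_h: np.ndarray | float) -> np.ndarray | float:
        raw = self.mesor_rate + self.amplitude_rate * np.cos(
            2.0 * np.pi * (np.asarray(zt_h, dtype=float) - self.acrophase_h) / self.period_h
        )
        return np.maximum(raw, 0.0)

    @property
    def peak_rate(self) -> float:
        return self.mesor_rate + self.amplitude_rate


@dataclass
class SimConfig:
    """Configuration for all three generators; unused blocks may stay None."""

    rate_per_s: float = 0.05
    session_length_s: float = 3000.0
    seed: int = 0
    burst_params: Optional[BurstParams] = None
    circadian_params: Optional[CircadianParams] = None
    schedule: Sequence[Tuple[float, float]] = field(default_factory=lambda: DEFAULT_SCHEDULE)

    def rng(self, offset: int = 0) -> np.random.Generator:
        return np.random.default_rng(self.seed + offset)


def _poisson_times(rng: np.random.Generator, rate: float, length_s: float) -> np.ndarray:
    """Homogeneous Poisson event times on [0, length) via count + order statistics."""
    n = rng.poisson(rate * length_s)
    return np.sort(rng.uniform(0.0, length_s, size=n))


def simulate_homogeneous_poisson(config: SimConfig) -> EventSeries:
    """Simulate one session of a homogeneous Poisson process.

    The inter-event intervals of the output are i.i.d. exponential with
    mean ``1/rate_per_s``; the expected event count is ``rate * length``.
    """
    if config.rate_per_s <= 0:
        raise ConfigError("rate_per_s must be positive")
    if config.session_length_s < 0:
        raise ConfigError("session_length_s must be non-negative")
    if config.session_length_s == 0:
        return EventSeries(np.empty(0), 0.0)
    times = _poisson_times(config.rng(), config.rate_per_s, config.session_length_s)
    return EventSeries(times, config.session_length_s)


def simulate_bursty_process(config: SimConfig) -> EventSeries:
    """Simulate one session of a Poisson cluster (Neyman–Scott) process.

    Parents arrive at ``cluster_rate_per_s``; each spawns a geometric
    number of events (mean ``mean_events_per_cluster``, minimum 1) whose
    successive gaps are exponential with scale ``intra_cluster_scale_s``.
    The union of all offspring, truncated to the session, is returned.
    Parents are drawn on a window extended to the left so clusters
    straddling the session start are represented without edge bias.
    """
    if config.burst_params is None:
        raise ConfigError("burst_params must be set for the bursty simulator")
    config.burst_params.validate()
    if config.session_length_s <= 0:
        raise ConfigError("session_length_s must be positive")
    bp = config.burst_params
    rng = config.rng()

    # Left-extend the parent window by several expected cluster spans.
    span = bp.mean_events_per_cluster * bp.intra_cluster_scale_s
    pad = 10.0 * span
    parents = _poisson_times(rng, bp.cluster_rate_per_s, config.session_length_s + pad) - pad

    p = 1.0 / bp.mean_events_per_cluster
    sizes = rng.geometric(p, size=parents.size)  # support {1, 2, ...}, mean 1/p
    all_times: List[np.ndarray] = []
    for t0, size in zip(parents, sizes):
        gaps = rng.exponential(bp.intra_cluster_scale_s, size=size - 1)
        all_times.append(t0 + np.concatenate(([0.0], np.cumsum(gaps))))
    times = np.sort(np.concatenate(all_times)) if all_times else np.empty(0)
    times = times[(times >= 0.0) & (times < config.session_length_s)]
    return EventSeries(times, config.session_length_s)


def theoretical_cluster_fano(params: BurstParams) -> float:
    """Fano factor of the cluster process for windows much longer than a cluster.

    For a Poisson cluster process with i.i.d. cluster sizes S the counts in
    long windows have Fano factor ``1 + E[S(S-1)]/E[S]``. With S geometric
    on {1,2,...} with mean m: E[S] = m, E[S^2] = m(2m-1), hence the long-
    window Fano factor is ``2m - 1`` (e.g. 9 for m = 5).
    """
    m = params.mean_events_per_cluster
    p = 1.0 / m
    e_s = m
    e_s2 = (2.0 - p) / p**2
    return 1.0 + (e_s2 - e_s) / e_s


def simulate_circadian_process(
    config: SimConfig, mouse_index: int = 0, mouse_id: Optional[str] = None
) -> List[EventSeries]:
    """Simulate scheduled detection sessions of a cosine-modulated Poisson process.

    Each ``(zt_start_h, duration_s)`` window of the schedule is sampled by
    Lewis–Shedler thinning against the peak rate: candidate events are drawn
    as a homogeneous Poisson stream at ``mesor + amplitude`` and accepted
    with probability ``lambda(t)/peak``. The expected count per session is
    the integral of the (clipped) rate over the window.
    """
    if config.circadian_params is None:
        raise ConfigError("circadian_params must be set for the circadian simulator")
    config.circadian_params.validate()
    if not config.schedule:
        raise ConfigError("schedule must contain at least one session window")
    cp = config.circadian_params
    rng = config.rng(mouse_index)
    mid = mouse_id if mouse_id is not None else f"m{mouse_index}"

    out: List[EventSeries] = []
    for k, (zt0, dur) in enumerate(config.schedule):
        if dur <= 0:
            raise ConfigError("session duration must be positive")
        if cp.peak_rate == 0:
            times = np.empty(0)
        else:
            cand = _poisson_times(rng, cp.peak_rate, dur)
            zt = zt0 + cand / 3600.0
            accept = rng.uniform(size=cand.size) < np.asarray(cp.rate_at(zt)) / cp.peak_rate
            times = cand[accept]
        out.append(
            EventSeries(
                times,
                duration_s=dur,
                mouse_id=mid,
                session_id=f"zt{zt0:g}",
                zt_start_h=float(zt0 % 24.0),
                schedule_label="LD12",
            )
        )
    return out


def simulate_circadian_cohort(config: SimConfig, n_mice: int) -> List[List[EventSeries]]:
    """Simulate ``n_mice`` independent animals; mouse *i* uses seed ``seed + i``."""
    if n_mice < 1:
        raise ConfigError("n_mice must be >= 1")
    return [simulate_circadian_process(config, mouse_index=i) for i in range(n_mice)]


def expected_session_count(params: CircadianParams, zt_start_h: float, duration_s: float,
                           n_grid: int = 10001) -> float:
    """Numerically integrate the clipped cosine rate over one session window."""
    t = np.linspace(zt_start_h, zt_start_h + duration_s / 3600.0, n_grid)
    lam = np.asarray(params.rate_at(t))
    return float(np.trapezoid(lam, t) * 3600.0)
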