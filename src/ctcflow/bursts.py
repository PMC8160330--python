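"""Burst classification of CTC event streams.

A burst is a run of two or more successive events whose connecting
inter-event intervals (ICIs) are all strictly smaller than the session's
mean ICI. The joint-ICI scatter — current ICI against next ICI, with the
mean ICI splitting both axes — assigns each interior event a role:

==============  ==============  ====================
current ICI     next ICI        role
==============  ==============  ====================
< mean          < mean          within a burst
< mean          >= mean         final event of a burst
>= mean         < mean          initial event of a burst
>= mean         >= mean         sporadic
==============  ==============  ====================

Burst events are the union of the within/initial/final roles; the
nonburst:burst ratio compares sporadic to bursting events. The first and
last event of a session have only one adjacent ICI and are labelled from
it (adjacent ICI below the mean makes them the initial/final member of
that run), so event counts are conserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy import stats

from .events import InsufficientDataError
from .intervals import IntervalSet

ROLES = ("within_burst", "initial_in_burst", "final_in_burst", "sporadic")


@dataclass
class BurstClassification:
    threshold_s: float
    labels: List[str]
    joint_pairs: np.ndarray  # shape (C-1, 2): (current ICI, next ICI)
    n_burst_events: int
    n_nonburst_events: int

    @property
    def nonburst_to_burst_ratio(self) -> float:
        """n_nonburst / n_burst; +inf (flagged via is_ratio_defined) when no bursts."""
        if self.n_burst_events == 0:
            return float("inf")
        return self.n_nonburst_events / self.n_burst_events

    @property
    def is_ratio_defined(self) -> bool:
        return self.n_burst_events > 0


@dataclass
class BurstComparison:
    t_statistic: float
    df: float
    p_value: float
    n_a: int
    n_b: int


def _interior_role(cur_below: bool, nxt_below: bool) -> str:
    if cur_below and nxt_below:
        return "within_burst"
    if cur_below and not nxt_below:
        return "final_in_burst"
    if not cur_below and nxt_below:
        return "initial_in_burst"
    return "sporadic"


def classify_bursts(intervals: IntervalSet) -> BurstClassification:
    """Label every event of a session by its burst role.

    The threshold is the session's mean ICI; "smaller than the mean" is
    strict, so a stream of perfectly regular events has no bursts at all
    (ratio undefined, reported as +inf).
    """
    icis = intervals.icis
    if intervals.n_events < 3 or icis.size < 2:
        raise InsufficientDataError("burst classification needs >= 3 events (>= 2 ICIs)")
    mean = float(icis.mean())
    below = icis < mean  # strict: ICIs equal to the mean do not join bursts

    labels: List[str] = []
    # first event: only ICI_1 is adjacent
    labels.append("initial_in_burst" if below[0] else "sporadic")
    for i in range(1, intervals.n_events - 1):
        labels.append(_interior_role(bool(below[i - 1]), bool(below[i])))
    labels.append("final_in_burst" if below[-1] else "sporadic")

    n_burst = sum(lab != "sporadic" for lab in labels)
    joint = np.column_stack([icis[:-1], icis[1:]])
    return BurstClassification(
        threshold_s=mean,
        labels=labels,
        joint_pairs=joint,
        n_burst_events=n_burst,
        n_nonburst_events=intervals.n_events - n_burst,
    )


def burst_membership_by_runs(intervals: IntervalSet) -> np.ndarray:
    """Boolean burst membership from run-length scanning of sub-mean ICIs.

    Independent of the quadrant labelling: an event is a burst member iff
    it touches at least one ICI below the mean (every maximal run of k
    sub-mean ICIs bridges k+1 events, and k >= 1 already makes a burst of
    two). Used as a cross-check of :func:`classify_bursts`.
    """
    icis = intervals.icis
    if icis.size < 2:
        raise InsufficientDataError("need >= 2 ICIs")
    below = icis < icis.mean()
    member = np.zeros(intervals.n_events, dtype=bool)
    member[:-1] |= below
    member[1:] |= below
    return member


def compare_burst_ratios(group_a: Sequence[float], group_b: Sequence[float]) -> BurstComparison:
    """Two-sided unpaired t-test between two groups of nonburst:burst ratios.

    Non-finite ratios (sessions without bursts) are excluded with a warning.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    fa, fb = a[np.isfinite(a)], b[np.isfinite(b)]
    if fa.size < a.size or fb.size < b.size:
        warnings.warn(
            f"excluded {a.size - fa.size + b.size - fb.size} non-finite ratio(s) "
            "from the group comparison",
            stacklevel=2,
        )
    if fa.size < 2 or fb.size < 2:
        raise InsufficientDataError("each group needs >= 2 finite ratios")
    res = stats.ttest_ind(fa, fb)
    df = fa.size + fb.size - 2
    return BurstComparison(
        t_statistic=float(res.statistic),
        df=float(df),
        p_value=float(res.pvalue),
        n_a=int(fa.size),
        n_b=int(fb.size),
    )
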