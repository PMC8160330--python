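"""Core event-stream container for in vivo flow cytometry detection sessions.

A detection session is an ordered list of CTC detection timestamps (seconds
from session start), optionally annotated per event with the peak height,
peak width and a single-cell/cluster flag extracted from the photodetector
trace. Session metadata (mouse, zeitgeber start time, light schedule) rides
along so downstream circadian fits can place the session on the 24-h clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

#: Closed vocabulary of light-schedule labels.
SCHEDULE_LABELS = ("LD12", "DD", "DL", "LD16_8")


class ConfigError(ValueError):
    """Raised when a simulation or analysis configuration is invalid."""


class InsufficientDataError(ValueError):
    """Raised when an operation is asked to run on too few events/intervals."""


@dataclass
class EventSeries:
    """One detection session's ordered CTC event times plus metadata.

    Parameters
    ----------
    timestamps
        Event times in seconds from session start, sorted ascending,
        all within ``[0, duration_s)``.
    duration_s
        Session length in seconds.
    mouse_id, session_id
        Identifiers; free-form strings.
    zt_start_h
        Zeitgeber time of session start in hours (ZT0 = lights-on). ``None``
        when the session is not part of a timed design.
    schedule_label
        One of ``LD12, DD, DL, LD16_8`` or ``None``.
    heights, widths_ms, is_cluster
        Optional per-event annotations (same length as ``timestamps``).
    """

    timestamps: np.ndarray
    duration_s: float
    mouse_id: str = "m0"
    session_id: str = "s0"
    zt_start_h: Optional[float] = None
    schedule_label: Optional[str] = None
    heights: Optional[np.ndarray] = None
    widths_ms: Optional[np.ndarray] = None
    is_cluster: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.timestamps.ndim != 1:
            raise ConfigError("timestamps must be one-dimensional")
        if self.duration_s < 0:
            raise ConfigError("duration_s must be non-negative")
        if np.any(np.diff(self.timestamps) < 0):
            raise ConfigError("timestamps must be sorted ascending")
        if self.timestamps.size and (
            self.timestamps[0] < 0 or self.timestamps[-1] >= self.duration_s > 0
        ):
            raise ConfigError("timestamps must lie within [0, duration_s)")
        if self.schedule_label is not None and self.schedule_label not in SCHEDULE_LABELS:
            raise ConfigError(
                f"schedule_label must be one of {SCHEDULE_LABELS}, got {self.schedule_label!r}"
            )
        for name in ("heights", "widths_ms", "is_cluster"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr)
                if arr.shape != self.timestamps.shape:
                    raise ConfigError(f"{name} must match timestamps in length")
                setattr(self, name, arr)

    @property
    def n_events(self) -> int:
        return int(self.timestamps.size)

    @property
    def zt_mid_h(self) -> Optional[float]:
        """Session midpoint on the zeitgeber clock, modulo 24 h."""
        if self.zt_start_h is None:
            return None
        return float((self.zt_start_h + self.duration_s / 3600.0 / 2.0) % 24.0)

    def count_in(self, start_s: float, end_s: float) -> int:
        """Number of events with ``start_s <= t < end_s``."""
        return int(
            np.searchsorted(self.timestamps, end_s, side="left")
            - np.searchsorted(self.timestamps, start_s, side="left")
        )

    def with_unit_scale(self, factor: float) -> "EventSeries":
        """Return a copy with all times multiplied by ``factor`` (unit change)."""
        return replace(
            self,
            timestamps=self.timestamps * factor,
            duration_s=self.duration_s * factor,
        )
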