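"""Readers and writers for the delimited-text event and session tables.

Event CSV schema (one row per detected event):

    mouse_id, session_id, t_s [, zt_start_h, duration_s, schedule_label,
    height, width_ms, is_cluster]

Session metadata CSV schema:

    mouse_id, session_id, day_post_implant, zt_start_h, schedule_label,
    duration_s [, source_file]

All times are seconds stored as decimals; zeitgeber times are hours; the
two never share a column.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .events import SCHEDULE_LABELS, EventSeries

REQUIRED_EVENT_COLUMNS = ("mouse_id", "session_id", "t_s")
OPTIONAL_EVENT_COLUMNS = ("zt_start_h", "duration_s", "schedule_label",
                          "height", "width_ms", "is_cluster")


class ValidationError(ValueError):
    """Raised when an input table violates the schema; names offending lines."""


def write_events(series_list: Sequence[EventSeries], path: str | Path) -> None:
    """Write one or more sessions to a single event CSV."""
    rows = []
    for s in series_list:
        for i, t in enumerate(s.timestamps):
            rows.append({
                "mouse_id": s.mouse_id,
                "session_id": s.session_id,
                "t_s": t,
                "zt_start_h": s.zt_start_h if s.zt_start_h is not None else "",
                "duration_s": s.duration_s,
                "schedule_label": s.schedule_label or "",
                "height": s.heights[i] if s.heights is not None else "",
                "width_ms": s.widths_ms[i] if s.widths_ms is not None else "",
                "is_cluster": int(s.is_cluster[i]) if s.is_cluster is not None else "",
            })
        if s.n_events == 0:  # keep empty sessions discoverable
            rows.append({
                "mouse_id": s.mouse_id, "session_id": s.session_id, "t_s": "",
                "zt_start_h": s.zt_start_h if s.zt_start_h is not None else "",
                "duration_s": s.duration_s,
                "schedule_label": s.schedule_label or "",
                "height": "", "width_ms": "", "is_cluster": "",
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_events(path: str | Path, duplicate_tolerance_s: float = 0.0) -> List[EventSeries]:
    """Read an event CSV into one EventSeries per (mouse_id, session_id).

    Malformed rows raise :class:`ValidationError` naming the offending
    CSV line number (header = line 1).
    """
    df = pd.read_csv(path, dtype={"mouse_id": str, "session_id": str})
    missing = [c for c in REQUIRED_EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")

    # line numbers in the file: header is line 1, first data row line 2
    df["_line"] = df.index + 2
    has_time = df["t_s"].notna()
    bad_neg = df.loc[has_time & (pd.to_numeric(df["t_s"], errors="coerce") < 0)]
    if len(bad_neg):
        raise ValidationError(
            f"{path}: negative timestamp at line(s) {bad_neg['_line'].tolist()}"
        )
    unparsable = df.loc[has_time & pd.to_numeric(df["t_s"], errors="coerce").isna()]
    if len(unparsable):
        raise ValidationError(
            f"{path}: non-numeric t_s at line(s) {unparsable['_line'].tolist()}"
        )

    out: List[EventSeries] = []
    for (mid, sid), grp in df.groupby(["mouse_id", "session_id"], sort=True):
        ev = grp.loc[grp["t_s"].notna()].sort_values("t_s")
        t = ev["t_s"].to_numpy(dtype=float)
        if t.size > 1 and duplicate_tolerance_s >= 0:
            dups = np.flatnonzero(np.diff(t) < -duplicate_tolerance_s)
            if dups.size:
                raise ValidationError(f"{path}: non-monotonic timestamps in {mid}/{sid}")

        def _opt_col(name, caster, source=ev):
            if name in source.columns and source[name].notna().all() and len(source):
                return source[name].map(caster).to_numpy()
            return None

        meta = grp.iloc[0]
        dur = float(meta["duration_s"]) if "duration_s" in grp.columns and pd.notna(
            meta["duration_s"]) else (float(t[-1]) + 1.0 if t.size else 0.0)
        zt = float(meta["zt_start_h"]) if "zt_start_h" in grp.columns and pd.notna(
            meta["zt_start_h"]) else None
        label = meta["schedule_label"] if "schedule_label" in grp.columns and pd.notna(
            meta["schedule_label"]) and meta["schedule_label"] != "" else None
        out.append(EventSeries(
            t, duration_s=dur, mouse_id=str(mid), session_id=str(sid),
            zt_start_h=zt, schedule_label=label,
            heights=_opt_col("height", float),
            widths_ms=_opt_col("width_ms", float),
            is_cluster=_opt_col("is_cluster", lambda v: bool(int(v))),
        ))
    return out


def write_sessions(rows: Sequence[Dict], path: str | Path) -> None:
    df = pd.DataFrame(rows)
    required = ["mouse_id", "session_id", "zt_start_h", "schedule_label", "duration_s"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"session table missing column(s) {missing}")
    df.to_csv(path, index=False)


def read_sessions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"mouse_id": str, "session_id": str})
    required = ["mouse_id", "session_id", "zt_start_h", "schedule_label", "duration_s"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    if df.duplicated(["mouse_id", "session_id"]).any():
        raise ValidationError(f"{path}: duplicate (mouse_id, session_id) rows")
    if (df["duration_s"] <= 0).any():
        raise ValidationError(f"{path}: non-positive duration_s")
    bad = ~df["schedule_label"].isin(SCHEDULE_LABELS)
    if bad.any():
        raise ValidationError(
            f"{path}: schedule_label outside {SCHEDULE_LABELS} at line(s) "
            f"{(df.index[bad] + 2).tolist()}"
        )
    return df
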