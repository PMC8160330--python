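#!/usr/bin/env python
"""Compare burst activity between the early-stage and late-stage streams.

Classifies every event by its joint-ICI quadrant role, computes each
session's nonburst:burst ratio, and tests the early-vs-late contrast with
an unpaired t-test (bursty streams should sit at lower ratios). Writes
results/burst_ratios.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ctcflow import classify_bursts, compare_burst_ratios, compute_icis
from ctcflow.io import read_events

RESULTS = Path(__file__).resolve().parent.parent / "results"
STREAMS = Path(__file__).resolve().parent.parent / "scratch" / "streams"


def main() -> None:
    rows, groups = [], {"late": [], "early": []}
    for stage, fname in (("late", "late_stage.csv"), ("early", "early_stage.csv")):
        for s in read_events(STREAMS / fname):
            iv = compute_icis(s)
            if iv.n_intervals < 2:
                continue
            bc = classify_bursts(iv)
            ratio = bc.nonburst_to_burst_ratio
            groups[stage].append(ratio)
            roles = pd.Series(bc.labels).value_counts().to_dict()
            rows.append({
                "stage": stage, "mouse_id": s.mouse_id,
                "mean_ici_s": round(bc.threshold_s, 2),
                "n_burst_events": bc.n_burst_events,
                "n_nonburst_events": bc.n_nonburst_events,
                "ratio": round(ratio, 3) if np.isfinite(ratio) else "inf",
                **{f"n_{k}": v for k, v in roles.items()},
            })
    df = pd.DataFrame(rows)
    out = RESULTS / "burst_ratios.csv"
    df.to_csv(out, index=False)

    res = compare_burst_ratios(groups["early"], groups["late"])
    m_e = np.mean([r for r in groups["early"] if np.isfinite(r)])
    m_l = np.mean([r for r in groups["late"] if np.isfinite(r)])
    print(f"nonburst:burst ratio — early {m_e:.2f} vs late {m_l:.2f} "
          f"(t={res.t_statistic:.2f}, df={res.df:.0f}, p={res.p_value:.3g})")
    print("lower ratio = larger share of events in bursts")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
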