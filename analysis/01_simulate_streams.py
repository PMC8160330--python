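#!/usr/bin/env python
"""Generate the synthetic study: event streams for every downstream analysis.

Produces, under scratch/streams/ (regenerable intermediates):

* late_stage.csv  — 5 mice, one 3000-s homogeneous Poisson session each at
  the late-stage intensity (151 events expected per session);
* early_stage.csv — 5 mice, one 3000-s Poisson-cluster (bursty) session
  each, rate-matched in expectation to 75 events (mid progression);
* cohort_<label>.csv — 8-mouse cohorts monitored 30 min every 4 h
  (ZT1..ZT21) under three light schedules: LD12 (peak ZT13), DL (inverted,
  peak ZT1) and LD16_8 (4-h delayed, peak ZT17).
"""

import argparse
from dataclasses import replace
from pathlib import Path

from ctcflow import SimConfig, simulate_bursty_process, simulate_homogeneous_poisson
from ctcflow.io import write_events
from ctcflow.simulate import BurstParams, CircadianParams, simulate_circadian_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"
STREAMS = Path(__file__).resolve().parent.parent / "scratch" / "streams"

COHORTS = {  # schedule label -> generating acrophase (ZT h)
    "LD12": 13.0,
    "DL": 1.0,
    "LD16_8": 17.0,
}


def main(seed: int) -> None:
    STREAMS.mkdir(parents=True, exist_ok=True)

    late = []
    for i in range(5):
        s = simulate_homogeneous_poisson(
            SimConfig(rate_per_s=151 / 3000, session_length_s=3000.0, seed=seed + i))
        late.append(replace(s, mouse_id=f"m{i+1}", session_id="day24"))
    write_events(late, STREAMS / "late_stage.csv")

    early = []
    bp = BurstParams(cluster_rate_per_s=0.005, mean_events_per_cluster=5.0,
                     intra_cluster_scale_s=2.0)
    for i in range(5):
        s = simulate_bursty_process(
            SimConfig(session_length_s=3000.0, seed=seed + 100 + i, burst_params=bp))
        early.append(replace(s, mouse_id=f"m{i+1}", session_id="day12"))
    write_events(early, STREAMS / "early_stage.csv")

    for label, acro in COHORTS.items():
        cp = CircadianParams(mesor_rate=0.04, amplitude_rate=0.03, acrophase_h=acro)
        cohort = simulate_circadian_cohort(
            SimConfig(seed=seed + 1000 * (1 + list(COHORTS).index(label)),
                      circadian_params=cp), n_mice=8)
        flat = [replace(s, schedule_label=label) for mouse in cohort for s in mouse]
        write_events(flat, STREAMS / f"cohort_{label}.csv")

    n_late = sum(s.n_events for s in late)
    n_early = sum(s.n_events for s in early)
    print(f"late-stage Poisson sessions: {n_late} events over 5 mice "
          f"(expected ~755)")
    print(f"early-stage bursty sessions: {n_early} events over 5 mice "
          f"(expected ~375)")
    for label in COHORTS:
        print(f"cohort {label}: 8 mice x 6 sessions -> "
              f"{STREAMS / f'cohort_{label}.csv'}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    main(ap.parse_args().seed)
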