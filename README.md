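# ctcflow

Point-process analysis of circulating tumor cell (CTC) detection streams
from in vivo flow cytometry (IVFC), plus the synthetic generators needed to
validate every stage without animal data.

## The problem

Fluorescence IVFC watches a mouse artery through a laser light sheet and
time-stamps every fluorescent tumor cell that passes, yielding an *event
stream*: ordered detection times over a 30–50 min session. Three questions
drive the analysis:

1. **Is CTC release a homogeneous Poisson process, or does it burst?**
   A Poisson stream has i.i.d. exponential inter-CTC intervals (ICIs) and a
   variance-to-mean ratio (Fano factor) of 1 for windowed counts. Departures
   — interval distributions outside the Kolmogorov–Smirnov band, Fano
   factors above the Poisson confidence interval, runs of sub-mean ICIs —
   indicate clustered ("bursty") release.
2. **Do CTC counts follow a circadian rhythm?** Counts from 30-min sessions
   every 4 h (ZT1…ZT21) are fit with a single-component cosinor,
   `y(t) = MESOR + A·cos(2π(t − φ)/24)`, and rhythm parameters are compared
   across light schedules (12:12 LD, constant darkness, inverted light,
   16:8 LD).
3. **How should one sample to count CTCs accurately?** Strategies using one
   or five 1-min windows with different spacings are scored by the mean
   deviation `|Ns − σ|/σ × 100%` from the full 30-min record.

The statistics implemented: exponential maximum-likelihood fit
`λ̂ = C/ΣICIᵢ` with the KS band `±1.36/√C` (exact Kolmogorov quantiles for
C < 35); the Fano factor with the χ² null interval
`[χ²₀.₀₂₅,N−1, χ²₀.₉₇₅,N−1]/(N−1)`; the joint-ICI quadrant rule for burst
roles (current/next ICI against the mean ICI); least-squares cosinor with a
zero-amplitude F-test and population-mean group comparisons (t-tests on
MESOR/amplitude, Watson–Williams on acrophase); and the sampling-strategy
accuracy metrics. Generators cover homogeneous Poisson, Neyman–Scott
cluster (bursty) and cosine-modulated inhomogeneous Poisson streams, plus
PMT-like traces with Gaussian spikes for the detection layer.

## Worked example

```python
from ctcflow import (SimConfig, simulate_homogeneous_poisson, compute_icis,
                     fit_exponential_mle, ks_exponential_band, fano_factor,
                     classify_bursts)

stream = simulate_homogeneous_poisson(
    SimConfig(rate_per_s=151/3000, session_length_s=3000, seed=1))
iv = compute_icis(stream)
fit = fit_exponential_mle(iv)
ks = ks_exponential_band(iv, fit)
fano = fano_factor(stream, window_length_s=100)
bursts = classify_bursts(iv)
print(f"{stream.n_events} events, mean ICI {iv.mean_ici_s:.1f} s, "
      f"lambda_hat {fit.lambda_hat:.4f}/s")
print(f"KS d_max {ks.d_max:.3f} vs d_crit {ks.d_crit_95:.3f} "
      f"-> within band: {ks.within_band}")
print(f"Fano {fano.fano:.2f}, Poisson 95% CI {fano.ci_95[0]:.2f}-{fano.ci_95[1]:.2f}")
print(f"nonburst:burst ratio {bursts.nonburst_to_burst_ratio:.2f}")
```

prints

```
151 events, mean ICI 19.8 s, lambda_hat 0.0505/s
KS d_max 0.052 vs d_crit 0.111 -> within band: True
Fano 0.53, Poisson 95% CI 0.55-1.58
nonburst:burst ratio 0.13
```

151 events in 3000 s at the simulated intensity; the interval distribution
stays inside the exponential KS band, i.e. this stream is consistent with a
Poisson process (this particular draw is slightly under-dispersed, with the
Fano factor just below the null interval — at the nominal 5% rate such
excursions are expected). About 63% of exponential ICIs fall below their
mean, so even a Poisson stream shows "bursts"; the analysis compares the
nonburst:burst *ratio* between conditions rather than asserting bursts are
absent.

## The analysis, end to end

Numbered drivers under `analysis/` run the full synthetic study over the
library in `src/ctcflow/` and write tables under `results/`:

* `00_trace_detection_demo.py` — events → synthetic PMT trace → detected
  spikes, with single/cluster discrimination;
* `01_simulate_streams.py` — late-stage Poisson sessions, early-stage bursty
  sessions, and three 8-mouse circadian cohorts (LD12, DL, LD16_8);
* `02_poisson_tests.py` — KS band + Fano per session (late stage: 5/5 inside
  the KS band, mean Fano 1.05; early stage: 0/5 inside, mean Fano 8.25);
* `03_burst_analysis.py` — nonburst:burst ratios (early 0.05 vs late 0.19,
  unpaired t-test p ≈ 4×10⁻⁴);
* `04_circadian_rhythm.py` — per-mouse cosinor fits: population acrophases
  ZT12.9 / ZT0.9 / ZT17.0 for LD12 / DL / LD16_8, i.e. a ~12-h inversion
  under DL and a ~4-h shift under 16:8 LD, both significant; peak/trough
  fold changes ≈ 7–8;
* `05_sampling_strategies.py` — mean deviation by strategy and time of day
  (e.g. strategy A: 39% at the ZT13 peak vs 103% at the ZT1 trough;
  multisampling roughly halves both).

A `ctcflow` command-line tool exposes the same stages
(`simulate`, `detect`, `intervals`, `bursts`, `cosinor`, `sampling`, `run`)
over CSV event tables; `ctcflow run --config pipeline.yaml --out dir`
executes a configured pipeline and writes a manifest with the package
version, config hash and seeds.

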