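# Methods

This note documents the models, estimators and numerical choices behind
`ctcflow`, and what the synthetic-data generators do and do not emulate.

## Event streams and the Poisson null

A detection session is modelled as a point process on `[0, T)`. The null
hypothesis throughout is a homogeneous Poisson process of intensity λ
(events/second): inter-event intervals (ICIs) are then i.i.d.
exponential, `F(x; λ) = 1 − e^{−λx}` for `x ≥ 0`, and counts in disjoint
windows are independent Poisson variables.

**Exponential MLE.** With C intervals, the log-likelihood
`L(λ) = C·log λ − λ·ΣICIᵢ` is maximized in closed form at
`λ̂ = C/ΣICIᵢ`. Zero-length intervals (two events in the same sample) are
retained; the exponential CDF handles `x = 0`. A property test confirms the
closed form against a dense grid search on every random instance.

**KS band.** The empirical ICI CDF is compared with the fitted exponential
CDF; the stream is accepted when the empirical curve stays entirely inside
the band `model ± d_crit(0.95)`, with `d_crit = 1.36/√C` asymptotically and
the exact two-sided Kolmogorov quantile (`scipy.stats.kstwo`) for `C < 35`.
`within_band` is equivalent to `D_max < d_crit`. The band is centred on the
CDF fitted to the *same* intervals — the comparison practitioners plot.
This makes the unadjusted band conservative (the Lilliefors effect): under
the null it contains the empirical CDF in ≈ 99–100% of replicates rather
than 95%. We document this rather than substituting Lilliefors-corrected
critical values, because the plotted band is the object of interest; the
test suite asserts coverage ≥ 95% and the acceptance script reports the
observed rate.

**Fano factor.** Counts in consecutive windows of `w` seconds (default
`w = 100` over a 3000-s session, i.e. 30 windows; only full windows are
used, and sensitivity across w ∈ {50, 100, 200} is part of the test
suite — the window length is a reporting choice, not a fitted quantity).
`FF = s²/mean` with the n−1 variance. Under the Poisson null
`(N−1)·FF ~ χ²_{N−1}`, giving the 95% interval
`[χ²₀.₀₂₅,N−1, χ²₀.₉₇₅,N−1]/(N−1)` — the standard spike-train construction.
Calibration at λ = 0.05/s, T = 3000 s: mean FF 1.006, CI coverage 94.9%
(1000 replicates; recomputed by `scripts/acceptance.py`).

## Burst classification

The burst threshold is the session's mean ICI; a burst is a maximal run of
≥ 2 events whose connecting ICIs are all *strictly* below the mean
("smaller than" is implemented as `<`, so perfectly regular streams have no
bursts and the nonburst:burst ratio is reported as +∞ with a flag rather
than dropped). Interior events are labelled from the joint-ICI pair
(current, next): both below → within burst; below/≥ → final event of a
burst; ≥/below → initial event; both ≥ → sporadic. The first and last
events carry only one adjacent ICI and inherit membership from it, so
event counts are conserved; this boundary convention is ours — joint-ICI
scatter plots simply omit those events — and it is configurable in the
sense that boundary labels are distinguishable in the output. An
independent run-length scanner reproduces the quadrant-derived membership
on every tested stream. For exponential ICIs, `P(ICI < mean) → 1 − e⁻¹ ≈
0.632`, so sub-mean intervals alone do not indicate bursting; only the
ratio contrast between conditions does. Group ratios are compared with
two-sided unpaired t-tests; non-finite ratios are excluded with a warning.

## Synthetic generators

All generators draw from a single `numpy` Generator seeded from the
configuration; per-mouse streams use `seed + mouse_index`. Fixed seeds give
bit-identical output.

* **Homogeneous Poisson**: event count ~ Poisson(λT), times uniform order
  statistics.
* **Bursty (Neyman–Scott / Poisson cluster)**: parents ~ Poisson(ρ), sizes
  geometric on {1, 2, …} with mean m, intra-cluster gaps exponential with
  scale τ. The parent window is extended left by 10·m·τ so clusters
  straddling the session start are represented. For windows much longer
  than a cluster the Fano factor is `1 + E[S(S−1)]/E[S] = 2m − 1` (= 9 at
  the default m = 5); with 100-s windows and ~8-s clusters the simulated
  mean is ≈ 8, well above the Poisson interval, and the ICI distribution
  leaves the KS band. The cluster mechanism itself is a modelling choice —
  burstiness is observed phenomenologically, not mechanistically — and a
  Markov-modulated Poisson process would be a reasonable alternative; the
  cluster process is the simplest generator with the right interval and
  count signatures. Defaults (ρ = 0.005/s, m = 5, τ = 2 s) put ~375
  events across five 3000-s sessions, an early/mid-progression regime.
* **Circadian inhomogeneous Poisson**:
  `λ(t) = max(0, M + A·cos(2π(t − φ)/24))` with t in zeitgeber hours
  (ZT0 = lights-on), sampled only inside scheduled windows by
  Lewis–Shedler thinning against the peak rate `M + A` — exact, with no
  discretization error. Negative modulated rates are clipped at zero and a
  warning is raised at validation. Defaults M = 0.04/s, A = 0.03/s,
  φ = ZT13 (one hour after lights-off under 12:12 LD, the observed peak),
  giving per-30-min session counts of mesor 72 and amplitude 54 and a
  peak:trough ratio of 7 — inside the reported 2–12-fold range. The
  reference schedule is six 30-min sessions every 4 h, ZT1…ZT21, 8 mice.
  Inverted-light (DL) and 16:8 LD cohorts are generated by shifting φ by
  12 h and 4 h; entrainment dynamics (transients during re-entrainment)
  are not modelled. Constant-darkness designs reuse the ZT field as
  circadian time with the schedule label disambiguating.
* **PMT traces**: each event adds a Gaussian pulse (amplitude 10, σ = 1 ms
  by default) on a flat baseline with white Gaussian noise; cluster events
  add 2–4 overlapping sub-pulses spaced `1.7 × FWHM` apart (≈ 4σ — wide
  enough that the valley between equal sub-pulses keeps sub-peak
  prominence above a 5σ detection threshold while staying above the
  hysteresis floor at SNR ≳ 20).

What the generators do **not** emulate: amplitude/width dependence on cell
velocity or vessel geometry, baseline drift and physiological artifacts,
photobleaching, inter-mouse rate heterogeneity beyond Poisson sampling,
and any coupling between burstiness and time of day. Passing tests
therefore show the estimators are calibrated and recover known parameters
under their assumed models — not that real recordings satisfy those
assumptions.

## Spike detection

Baseline = running median (default 201 samples; the window must exceed
twice the span of the widest expected signal, so multi-peak cluster
analyses at 10 kHz use ~1000 samples). Noise σ = 1.4826·MAD of the
baseline-subtracted trace, overridable for noiseless synthetics. Candidate
signals are contiguous runs above `θ/2` containing at least one sample
above `θ = threshold_sigma·σ` (hysteresis keeps noise from splitting one
excursion into several detections); default threshold 5σ, giving a
false-positive rate consistent with the Gaussian tail (≈ 0.3 expected
crossings per 10⁶ independent samples). Within a region, local maxima
separated by ≥ `min_separation_ms` (default 0.5 ms at the 100-kHz design
rate; scaled up when pulses are wider) with prominence ≥ θ count as
sub-peaks; a region with ≥ 2 sub-peaks is one *cluster* detection,
timestamped at the region's global maximum, height = baseline-subtracted
maximum, width = FWHM of the excursion by linear interpolation. Note a
geometric constraint: with equal-amplitude sub-pulses, simultaneous region
connectivity (valley > θ/2) and sub-peak prominence (peak − valley ≥ θ)
require peak amplitudes ≳ 2θ, i.e. SNR ≈ 2× the threshold; cluster
discrimination degrades gracefully to single-peak calls below that.

## Cosinor rhythmometry

Counts are normalised to events per 30 min and placed at session midpoints.
The fixed-24-h cosinor is linear least squares on `[1, cos ωt, sin ωt]`;
amplitude `A = √(β_c² + β_s²)`, acrophase `φ = atan2(β_s, β_c)/ω mod 24`
(time of the fitted maximum, on [0, 24)). Rhythmicity is the zero-amplitude
F-test, `F = ((SSE₀ − SSE₁)/2)/(SSE₁/(n − 3))` with 2 and n−3 degrees of
freedom; under flat-rate simulations its rejection rate at α = 0.05 is
calibrated within ±2 points. Six distinct timepoints leave 3 residual df —
enough for the F-test, though with limited power at small amplitudes.

Group comparisons are population-mean style: each animal contributes one
fitted parameter set; MESOR and amplitude are compared by unpaired
t-tests on the per-animal estimates, and acrophases — circular quantities —
by a Watson–Williams F-test (von Mises concentration estimated from the
mean resultant length, the classical 1 + 3/(8κ) correction), with the
group difference reported on the shorter arc of the 24-h circle.
Zero-amplitude fits carry no phase and are excluded with a warning. This
replaces meta-analytic rhythm-detection packages deliberately: with a
single fixed period and per-animal fits, the classical cosinor plus
parameter-level tests is the transparent equivalent.

Peak/trough fold change uses the sessions nearest the fitted acrophase and
acrophase + 12 h (sessions sit at ZT x.25, slightly off the true extrema,
biasing the estimate a little toward 1); a zero trough mean yields an
infinite fold change with a flag. The width–count correlation reports
Pearson r, r², and the adjusted R² of the one-predictor fit separately,
because the three are easy to conflate in figure annotations and adjusted
R² is legitimately negative for null relationships.

## Sampling strategies

Strategy A takes one 1-min window; B, C, D take five 1-min windows with
0-, 1- and 5-min gaps (spans 5, 9, 25 min). The placement start is uniform
over feasible integer-second starts of a 30-min record; records shorter
than a strategy's span are rejected rather than wrapped. The estimate
`Ns` is the mean per-window count and the reference σ is the full-record
mean count scaled to the same window length, making
`|Ns − σ|/σ × 100%` well-defined for both 1- and 5-min readouts; B's
estimate equals the single 5-min count divided by 5 by construction. The
replicate CV is Std/mean of the `Ns` draws. For Poisson records the
relative error of a w-min window scales as `1/√(λw)`, so higher-rate
(peak-time) records and longer effective windows both reduce the mean
deviation; the B/C/D ordering is close at equal total volume, with wider
spacing helping slightly through decorrelation, and is verified by Monte
Carlo rather than assumed.

## Problem sizes and determinism

Calibration loops use 300–1000 replicates of 3000-s sessions (standard
errors a few tenths of a percent on coverage rates); acrophase recovery
uses 20 cohorts of 8 mice. These sizes put Monte-Carlo noise well inside
the stated tolerances. All randomness flows from explicit seeds; the
pipeline manifest records the package version, config hash and seed, and
a rerun with the same config is byte-identical.

## Known limitations

* The KS band's conservativeness under same-data fitting is documented,
  not corrected (see above); comparisons of within-band *rates* between
  conditions remain valid, absolute rates are optimistic under the null.
* The Watson–Williams test assumes comparable concentrations and roughly
  von Mises phase spread; with n = 8 animals per group it is adequate for
  large shifts (4–12 h) but not a small-shift instrument.
* Burst labels depend on the session mean ICI, so they are not invariant
  under session truncation; unit rescaling, however, leaves them unchanged
  (tested).
* The trace layer models detection, not optics: no velocity-dependent
  pulse shapes, no baseline drift, no saturation.
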