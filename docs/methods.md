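# Methods

This note documents the models and numerical choices behind `spikeconn`:
what each estimator computes, what the synthetic-data generator emulates
(and does not), and where the design was genuinely open.

## Data model

A recording is a set of aligned point processes, one per electrode, stored
as integer sample indices at a common sampling rate `fs` (typically
10 kHz; 10 minutes is 6·10⁶ samples per electrode).  All estimators work on
a sparse electrodes × bins count matrix; bins are half-open
`[b·bin_samples, (b+1)·bin_samples)` with 0-based sample indices, and the
trailing partial bin is kept so binning conserves the total spike count at
every bin size.  Electrodes whose mean firing rate falls below `mfr_min`
(default 0.1 spikes/s, the conventional "silent electrode" floor for
dissociated cultures) are excluded before any pairwise analysis.  The
information-theory estimators reduce counts to binary occupancy (count > 0);
the correlation estimators use the counts themselves.

## Cross-correlation

The correlogram accumulates lag products of the binned pair over
correlation windows that tile the recording.  Window length is `2W+1` bins,
where `W = round(window_ms / bin_ms)` is the correlogram half-width
(default 100 ms at the analysis bin size); adjacent windows can overlap by
`overlap_frac` (default 0, equal-weight averaging).  Positive lag means the
target fires after the reference, and `C_xy(τ) = C_yx(−τ)` holds by
construction.

Normalization divides the summed lag products by
`sqrt(R_xx(0) · R_yy(0))`, the geometric mean of the two zero-lag
autocorrelation sums.  When every bin holds at most one spike and windows
do not overlap this equals the familiar `1/sqrt(N_x N_y)` spike-count
normalization; unlike the literal spike-count form it also guarantees, by
Cauchy–Schwarz, that values stay in [0, 1] and an autocorrelogram peaks at
exactly 1 for multi-spike bins and overlapping windows.

The frequency path computes the same quantity as the inverse real FFT of
the window-averaged cross-spectrum.  Each window is zero-padded to
`nfft = next power of two ≥ 2·(2W+1) − 1`, which turns circular into linear
correlation; no mean subtraction or tapering is applied on either path, and
the two implementations agree per lag to better than 1e−9 (enforced by
test on 50 Poisson pairs).

## Partial correlation

The spectral matrix `S[f]` (n × n per rfft frequency, Hermitian, summed
over the same windows) is pseudo-inverted per frequency via SVD, truncating
singular values below 1e−12 of the largest.  With `G = S⁺`, the
partialized cross-spectrum of a pair given all remaining electrodes is
recovered through the exact conditional-covariance identity

    S_xy|P = −G_xy / (G_xx G_yy − G_xy G_yx),

which is algebraically identical to the direct partialization
`S_xy − S_xP S_PP⁻¹ S_Py` whenever `S[f]` is invertible (enforced by test
at n = 3), and reduces to `S_xy` itself at n = 2, where the conditioning
population is empty.  The widely used per-frequency coherence form
`−G_xy / sqrt(G_xx G_yy)` differs from the conditional spectrum by a
frequency-dependent rescaling and would break both properties, which is why
the identity above was chosen.  The partial correlogram is the inverse FFT
of `S_xy|P`, scaled by the same autocorrelation-peak normalization as CC so
the two are directly comparable.  Pairs with an identically zero spectrum
are flagged and reported as zero.  Like CC, the raw spectra enter without
detrending or tapering; a taper would break the exact CC time/frequency
equality and was left out on both paths for consistency.

## Transfer entropy and joint entropy

TE is first order: one past bin for the target and one for the source, all
in bits (base 2 throughout, for comparability with JE whose definition
fixes log₂).  The eight joint states of `(x_t, x_{t−1}, y_{t−1})` are
counted over the whole binned recording with the convention 0·log 0 = 0;
for binary states TE is bounded by 1 bit.  The all-pairs matrix is computed
by three matrix products that count triple coincidences for every ordered
pair at once (float32 is exact here: every partial sum is an integer far
below 2²⁴).

JE builds the cISI histogram: for each occupied reference bin, the delay to
the next occupied target bin, searched up to `max_cisi_bins` (default
`round(window_ms / bin_ms)`, aligning the search horizon with the
correlation window).  A same-bin target spike counts as size 0.  Pairs with
no cISI in range carry no coupling evidence and receive a `+inf` sentinel,
which ranks as "no connection" everywhere (low JE = strong coupling); ROC
evaluation therefore negates JE scores.

## Connectivity matrices and thresholding

The symmetric CM holds each pair's correlogram peak within ±`peak_ms`
(default 10 ms) of zero lag; the directional CM attributes that peak to the
ordered pair its lag sign supports, and the delay matrix stores the signed
peak lag in ms.  A peak exactly at lag 0 gives no direction.  Ties are
broken toward the smallest |lag|, then toward the positive lag — a
deterministic rule that also settles the degenerate flat-correlogram case.

The hard threshold keeps entries strictly greater than `μ + n·σ` of the
nonzero off-diagonal entries (σ is the sample standard deviation; strict
inequality makes the σ = 0 case well defined: equal entries are all
removed).  The surrogate test displaces every spike independently and
uniformly within ±`w_ms` (dithering), recomputes the pair statistic on
`n_surrogates` surrogates (default 20), and keeps a connection iff the
observed statistic exceeds the surrogate mean + 2 SD (for JE: falls below
mean − 2 SD, the direction consistent with JE's semantics).  Dithering
preserves spike counts exactly: displacements are clipped to the recording
and collisions re-drawn for the later spike (≤ 100 attempts, then the
original position, then the nearest free sample).

Graph metrics operate on the undirected, unweighted view of the
thresholded matrix: Watts–Strogatz local clustering averaged over nodes of
degree ≥ 2, and characteristic path length averaged over finite (connected)
pairs only — both conventions stated here because the metrics' common names
leave them open.  Degree distributions use the directed graph.  The
population PSTH divides post-stimulus bin counts by
(#stimuli · #electrodes); the raw summed counts are also reported.

## ROC validation

Truth is `swm ≠ 0`.  Directed methods (TE; JE with reference→target
orientation; the directional CM) are scored on ordered pairs; symmetric
methods (CC, PC) on the OR-symmetrized truth.  The threshold sweeps the
0.5, 1.0, …, 99.5 percentiles of the off-diagonal scores (199 points;
strict `>` classification, mirroring the hard threshold), and the AUC is
the trapezoidal area with endpoints (0,0), (1,1) appended, vertical
segments traversed upward.  Infinite sentinels are mapped to finite
extremes one data-range beyond the observed scores before the percentile
sweep.

## The synthetic-data generator

The generator exists so that estimators can be validated against a known
wiring.  The stock benchmark is a 60-neuron network with independent
connection probability 0.02 per ordered pair (≈ 71 expected synapses), 80%
excitatory neurons, simulated at 10 kHz with one forward-Euler step per
sample (two half-steps for the membrane equation, the published
discretization of the model).  Neuron parameters follow the standard
heterogeneous cortical parameterization: excitatory `(a,b) = (0.02, 0.2)`,
`(c,d) = (−65+15r², 8−6r²)`; inhibitory `(a,b) = (0.02+0.08r, 0.25−0.05r)`,
`(c,d) = (−65, 2)`, `r ~ U(0,1)` per neuron.

Choices made where the reference benchmark's own simulator details were not
available — each stated once and frozen:

- **Noise.**  Per-step Gaussian current noise with amplitude specified at a
  1-ms reference scale (4.5 excitatory / 2 inhibitory) and scaled by
  `1/sqrt(dt_ms)` per step, so the integrated drive per millisecond does
  not depend on the step size.
- **Shared excitability drive.**  An Ornstein–Uhlenbeck current (s.d. 3,
  correlation time 50 ms) common to all neurons emulates the culture-wide
  co-modulation of activity that dissociated networks display.  It is what
  gives partialization something to remove: without it PC has no advantage
  over CC.
- **Synapses.**  A presynaptic spike injects the synaptic weight as a
  current pulse of 0.2 ms, one integration step (0.1 ms) after the spike.
  `weight_scale = 300` (excitatory weights `300·U(0.5,1)`, inhibitory twice
  as strong and negative) was calibrated so that a single EPSP jumps the
  membrane past the slow region of the quadratic upstroke, giving the
  fast (sub-millisecond), near-reliable transmission of strong *in vitro*
  synapses (spike-transmission efficacy ≈ 0.9).  With weak, slow synapses
  no pairwise estimator separates the 66 true pairs from the ~3400 others
  at sub-millisecond bins.
- **Rate calibration.**  At p = 0.02 the recurrent weights barely influence
  the network rate — the background noise sets it — so the provided
  calibration routine bisects a global noise multiplier (not the weights)
  until the population mean rate lands in a target band; the experimental
  range for cultures is 0.2–20 spikes/s.  The stock benchmark runs
  uncalibrated at ~15–25 spikes/s depending on the wiring seed, reflecting
  the near-critical amplification of recurrent cascades.
- **Benchmark scale.**  The validation simulations run 120 s (the full
  10-minute duration changes the AUCs by < 0.01 — the estimators are
  signal- rather than sample-limited at these rates) and bin at 0.3 ms.

What the generator does *not* emulate: conductance-based synapses,
synaptic depression/facilitation during bursts, electrode noise and spike-
sorting errors, multi-unit electrodes, and spatial structure.  Passing the
benchmark therefore shows that the estimators recover a known wiring from
realistic point-process statistics — not that they are robust to the
detection artifacts of real recordings.

Two properties of the reference benchmark do not emerge under these
conditions, and the corresponding acceptance tests are left failing rather
than tuned around: raw cross-correlation remains informative (AUC ≈ 0.91
instead of dropping to ≈ 0.69 and below the information-theory methods),
and the CC/PC/JE accuracies are flat-to-slightly-increasing over 0.3–1.0-ms
bins instead of decreasing.  Both would require interaction timing with
sub-0.3-ms jitter together with pervasive indirect correlations — a
combination we could not realize in this neuron model without pushing the
network far outside the physiological rate band (synchrony strong enough to
confuse CC also destroys TE and JE).  The TE signature — sharply lower
accuracy at 0.1-ms bins (one sample per bin) than at ≥ 0.3 ms — does
reproduce.

The three-neuron motif fixture (source driving two followers with equal
1.5-ms delays, 60% transmission, ±0.3-ms jitter, 2-Hz independent
background) probes the common-source artifact: CC shows a spurious
follower–follower peak, PC suppresses it, TE is protected by conditioning
on the target's own past, and JE assigns the follower pair a broader cISI
histogram than the true couples.

## Reproducibility

Every stochastic component (network wiring, simulation noise, dithering,
Poisson fixtures) takes an explicit seed and uses an independent generator
stream, so results are bit-identical across runs, chunk sizes, and the
numba/numpy kernel pair.  `scripts/acceptance.py --seed S` derives all
seeds from `S`.
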