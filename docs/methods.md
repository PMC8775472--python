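# Methods

This note documents the models, parameter choices and numerical
conventions behind `somnostage`, and what the synthetic-data tests do and
do not establish about real recordings.

## Synthetic polysomnography

### Architecture model

A night is generated as a semi-Markov bout process: the sleeper dwells in
a stage for a sampled number of 30-s epochs, then jumps according to an
embedded transition chain. Per-epoch Markov chains fragment the hypnogram
unrealistically; dwell-then-jump dynamics produce consolidated bouts and
recognisable NREM/REM cycles. The components are:

* **Sleep onset.** SOL is drawn from a normal distribution (default
  30 ± 7 min, truncated at 0) and realised exactly on the epoch grid: the
  pre-sleep run is wake followed by an N1 run, and the first N2 epoch
  falls at the sampled SOL. Entering N2 is the operational definition of
  falling asleep.
* **A forced deep first cycle** (N2→N3→N2→N3→N2→REM, with first-cycle
  dwell multipliers > 1). This guarantees at least one complete
  N1→N2→N3→REM cycle in any recording of ≥ 3 h and delays the first REM
  period to ≈ 0.8–0.9 h after the first N1, matching the front-loading of
  slow-wave sleep in healthy nights.
* **The bout chain.** Default mean dwells (epochs): N1 8, N2 15.7, N3 14,
  REM 14.3, wake 2.5, with dwell CV 0.2; transition weights route
  N2→{N3, REM}, N3→N2/REM, REM→{N2, N1, N0}. Dwell means were solved from
  the embedded chain's stationary distribution so that expected stage
  occupancies match an adapted healthy night: N1 ≈ 6 %, N2 ≈ 48 %,
  N3 ≈ 23.5 %, REM ≈ 22.5 % of TST (`with_stage_targets` re-solves them
  for any target mix).
* **Homeostatic pressure** (gain 1.0, configurable). The entry weights of
  N3 and REM are scaled by exp(deficit), the deficit being
  (expected − accrued) stage time in units of one mean bout. This mimics
  declining slow-wave pressure as SWS accrues and is what keeps
  night-to-night stage percentages tight: without it the generator's N3%
  SD across nights is ≈ 3.6 points; with it ≈ 1.0, in line with the 1–2
  point spread reported for adapted nights. N3 dwells drift shorter and
  REM dwells longer across the `n_cycles` nominal cycles of the night.
* **Morning wake.** A terminal wake run (default 42 ± 14 min) ends the
  night, putting TST near 7.9 h and SE near 87 % for a 9-h collection.
* **Short recordings.** `ArchitectureParams.scaled_to(tsc)` shrinks
  latencies linearly with TSC and dwells with sqrt(TSC/9 h), so a 1-h
  recording still traverses all five stages several times. This is the
  configuration used for the staging experiments in the test suite.

A realised 9-h night under the defaults gives (mean ± SD over 100 nights)
N1 6.4 ± 1.5, N2 48.3 ± 1.9, N3 22.3 ± 1.0, REM 22.9 ± 1.2 % of TST,
SE 87.6 ± 3.0 %, SOL 29.3 ± 6.8 min, WN 0.4 ± 0.6 — squarely in the range
of a healthy adapted cohort.

### Group effect

`GroupEffect` shifts the exposed arm's generative parameters additively:
Δ(mean N3 bout), Δ(mean N2 bout), Δ(SOL mean, min), and a target SE gain
realised by removing the corresponding wake time from the morning tail.
`GroupEffect.reference()` (+1.5 N3 epochs, −0.6 N2 epochs, −4.76 min SOL,
+3.5 SE points) reproduces the magnitude of the exposure contrast the
package is designed to analyse: ≈ +2 N3 percentage points, ≈ −1.5 N2
points, ≈ −5 min SOL.

### EEG synthesis

Each EEG channel is a sum over six bands (Kc 0–1.5, δ 1.5–4, θ 4–8,
α 8–13, β 13–25, γ 25–40 Hz) of unit-variance band-limited Gaussian noise
scaled by the current stage's band amplitude. Gains follow the hypnogram
but are smoothed with a ~1-s window, so the signal is continuous across
epoch boundaries. Stage signatures are deliberately separable with a
unique dominant band per stage — wake→α, N1→θ, N2→sub-δ (with 13.5-Hz
spindle bursts and biphasic K-complexes at 3 and 1.5 events/min), N3→δ,
REM→β — plus a broadband noise floor (1.5 µV). Two EOG channels carry
roughly antiphase slow-eye-movement waves during wake and REM, a fraction
of which (8 %) leaks into the EEG channels to exercise the ocular-artifact
removal.

**What this does not emulate:** real inter-subject variability of spectra,
stage-transition ambiguity (the main source of human scorer disagreement),
movement/ECG/sweat artifacts, and electrode drift. Staging accuracy on
this generator is therefore an upper bound and a correctness check of the
pipeline — held-out-subject accuracy here does not predict accuracy on
clinical recordings.

## Preprocessing

Fixed order: resample to 100 Hz (polyphase, anti-aliased; upsampling is
refused) → zero-phase 4th-order Butterworth band-pass 0.5–40 Hz
(forward–backward, so K-complex morphology is not phase-distorted; ≥ 20 dB
attenuation at 0.1 and 49 Hz, < 1 dB ripple at 10 Hz) → optional bad-channel
repair by inverse-distance-weighted neighbour averaging on 10–20 layout
coordinates (uniform weights when positions are unknown) → optional ICA
ocular-artifact removal → segmentation into 30-s epochs, dropping the
trailing partial window (whole epochs only, per scoring convention).

The ICA step uses FastICA with one component per EEG channel (reduced to
the numerical rank), rejecting any component whose |Pearson r| with an EOG
channel exceeds 0.8 (configurable). This correlation rule is the simplest
reproducible stand-in for manual component inspection; rejecting a
component can only reduce per-channel variance because estimated sources
are in-sample uncorrelated.

## Features

* PSD: Welch, 4-s Hann segments, 50 % overlap (0.25 Hz resolution) —
  standard for 30-s sleep epochs. Band "density" is the mean PSD in the
  band (µV²/Hz); integrated band power is available by configuration.
* Skewness/kurtosis use the 1/(N−1) normalisation (so Gaussian K ≈ 3, not
  0); the conventional 1/N estimator is a config flag.
* Entropies: SampEN and FUEN compare the N−m templates starting at
  0 … N−m−1 for both template lengths (the standard comparable-count
  convention), Chebyshev distance, self-matches excluded. When no pair
  matches at length m+1, SampEN returns the finite-sample cap
  −ln(2/((N−m−1)(N−m))) instead of infinity. MSES coarse-grains by
  non-overlapping τ-sample means and anchors r to the *original* series'
  SD (the usual multiscale convention; configurable). FUEN is evaluated on
  the SD-normalised epoch with absolute r = 0.3, making the feature
  amplitude-invariant — with membership exp(−d^n/r) and n = 2, tying r to
  the SD alone would not be. The O(N²) pair scans are numba-compiled;
  pairs whose membership would be < e⁻⁴⁵ skip the exponential, which is
  3×10⁻²⁰ per pair and far below the 10⁻¹² oracle-equality tolerance the
  tests enforce.
* Degenerate inputs: a flat epoch reports S = K = 0 and zero entropies
  with a flag; an all-zero spectrum reports f_c = 0 with a flag.

## Staging

Per training fold: CART (Gini) importance ranking → top-8 subset →
per-feature z-scoring → five stage-vs-rest RBF SVCs (C = 1,
γ = "scale", inverse-frequency class weights) wrapped in sigmoid (Platt)
calibration. Prediction is the argmax of the five calibrated
probabilities; exact ties resolve to the earlier stage in the fixed order
(N0, N1, N2, N3, REM) for determinism. A stage absent from training gets a
constant-low-probability scorer and a warning. Cross-validation is
grouped by subject; folds must not outnumber subjects. No temporal
smoothing is applied by default (`median_smooth` is available).

The permuted-label control doubles as a leakage detector: with labels
shuffled, calibrated scorers collapse to class priors and the argmax
predicts the majority class, so held-out accuracy equals the majority
rate — any excess would indicate information crossing the fold boundary.

## Group statistics

"Two-sample t" is the pooled-variance independent t test (Welch by flag);
the comparison table reports the difference as sham − exposed with its t,
p and 95 % CI oriented the same way, plus a percentile bootstrap CI
(B = 1000, within-group resampling, seeded). Percentage metrics are
exported as proportion differences at 3 decimals, mirroring the
conventional table formatting. The unit of analysis is the per-subject
mean over nights (avoiding pseudo-replication; per-night analysis is one
flag away). No multiple-testing correction by default; Holm is available.
Relative changes are computed against the sham mean:
(sham − exposed)/sham for decreases, (exposed − sham)/sham for increases.

WN (awakening number) is defined here as the count of maximal wake runs
strictly after sleep onset and before the final non-wake epoch — lights-on
wake and the morning run are not awakenings. Under the calibrated
generator WN is small and discrete (most nights 0 or 1), so t-tests on WN
are conservative; the null-calibration check in the acceptance suite is
therefore asserted on the continuous metrics.

REM latency is reported both as RL (hours) and RL% = RL/TST × 100; tables
that mix the two are ambiguous, so both are always computed.

## Problem sizes in the test and acceptance runs

Staging experiments use 20 subjects × 1 h (2400 labelled epochs) with
10-fold subject-grouped CV; effect-recovery uses 50 replicate cohorts of
21 + 20 subjects × 2 nights on ground-truth hypnograms, the null
calibration 200 replicates, and bootstrap coverage 200 cohorts at
B = 1000. These sizes give Monte-Carlo error comfortably inside the
asserted tolerances while keeping a full run in the tens of minutes on a
single CPU.

## Known limitations

* The generator's stage signatures are cleaner than real EEG; see above.
* SOL is anchored at lights-off = recording start by default.
* The ICA correlation rule removes only ocular activity that actually
  correlates with the recorded EOG channels.
* The γ band (25–40 Hz) abuts the 40-Hz filter edge, and the Kc band
  (0–1.5 Hz) overlaps the 0.5-Hz high-pass edge; both are computed on the
  filtered PSD as defined, so their absolute densities are attenuated
  near the edges.
* Writing EDF is not supported (no writer dependency); recordings persist
  as NPZ + JSON sidecars, and EDF reading is available via the optional
  `mne` extra.
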