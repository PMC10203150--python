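# Methods

This note documents the models, defaults and design choices of
`delmep-toolkit`, and what the synthetic benchmark does and does not show
about real TMS-EMG data.

## Problem and data model

An epoch is one EMG trace time-locked to a TMS pulse (pulse at t = 0 ms),
sampled at `fs_hz` (3000 Hz throughout the defaults, matching a 3 kHz
acquisition chain with a 10–500 Hz hardware band-pass). The quantity of
interest is the MEP onset latency in ms post-stimulus. Peak-to-peak
amplitude V_PP is computed on the post-stimulus window only (the onset-
bearing signal is post-stimulus; the pre-stimulus baseline would only add
noise to the statistic) and partitions epochs into low (≤ 100 µV), medium
(100–200 µV) and high (> 200 µV) strata.

Epochs with muscle pre-activation — any pre-stimulus sample exceeding
±15 µV within 1 s before the pulse — can be rejected with
`screen_preactivation`. The rule is *strictly greater than* 15 µV: a
sample at exactly the threshold passes. The screen is opt-in in the CLI
(`preprocess --screen`) because the synthetic generator models the
*retained* epochs of a study (see below), whose baseline noise level would
otherwise trip a literal max-based screen on almost every trace.

## Preprocessing

Four stages, in order:

1. **Trim** to the half-open window [10, 50) ms post-stimulus. Half-open
   gives exactly `round(40 ms · fs / 1000)` = 120 samples at 3 kHz (a
   closed window would give 121). Samples before 10 ms carry the stimulus
   artifact; samples after 50 ms carry no onset information.
2. **Smooth** with a 3-sample moving average. The window is *centered* and
   shrinks at the edges, so the output has the same length and no phase
   shift; a trailing window would bias every detected onset late by about
   one sample.
3. **Center** by subtracting the mean of the first 15 samples (5 ms),
   counteracting low-frequency baseline offset. Idempotent; preserves all
   pairwise sample differences.
4. **Normalize** min–max to [0, 1]. Flat traces (range ≤ 1e−9 µV) raise a
   degenerate-trace error rather than being passed through: normalization
   is undefined for them and a no-response epoch has no latency to
   annotate.

The composition is exactly invariant to a positive gain on the raw trace,
and invariant to an offset applied after the baseline window up to the
centering step. This is what lets one network annotate MEPs whose
amplitudes span two orders of magnitude.

Non-3 kHz inputs are accepted by every stage (the trim length follows the
rate), but the network input must be 120-dimensional; the CLI refuses to
annotate other lengths rather than silently resampling.

## The latency network

Fully connected 120 → 30 → 30 → 1, ReLU hidden activations, linear output
in ms (no clipping), 4591 trainable parameters, Glorot-uniform
initialization from a single integer seed. Training: Adam (lr 1e−3,
β₁ 0.9, β₂ 0.999) on mean-squared error, mini-batches of 32, a hard cap
of 200 epochs, and early stopping when a 10 % validation split has not
improved for 20 epochs; the best-validation weights are returned. MSE is
the training loss; MAE is the reporting metric. Setting
`validation_fraction = 0` disables early stopping (used for memorization
checks). The implementation is plain numpy (forward, backprop, Adam), so
same-platform fixed-seed runs are bit-reproducible; cross-platform bitwise
identity is not promised. Models serialize to a JSON container (spec +
nested weight lists) that is portable and diff-able.

## Rule-based estimators

All four consume the *trimmed raw* trace (µV, 10–50 ms window); a sample
index i converts to latency 10 + 1000·i/fs ms.

* **Signal Hunter**: smooth (window 3), first difference, score
  |Δx| − SD(Δx), take the first argmax, subtract the magic number
  (5 samples). The SD term is constant and cannot move the argmax; it is
  applied literally for fidelity to the published description.
* **AHTE**: threshold V_thr = 10 % of max|x|; first index with
  |x| ≥ threshold (inclusive crossing), minus 5 samples.
* **SHTE**: identical on x², threshold 10 % of max(x²). Relative to the
  amplitude this is a √0.1 ≈ 31.6 % threshold, so SHTE never crosses
  before AHTE.
* **Bigoni's method**: on |x|, first differences up to the global peak;
  the onset is the first sample of the longest run of consecutive strictly
  positive differences; among equal-length runs the earliest wins (onset
  semantics favour the first deflection). Runs shorter than 5 samples
  discard the epoch. No magic-number offset.

A negative index after magic-number subtraction discards the epoch rather
than extrapolating a latency before the analysis window. All four
estimators are invariant to positive gain.

## Synthetic epoch generator

The generator emulates the retained (artifact-screened) epochs of a
multi-subject TMS study with exactly known onsets. Per trace:

* **Waveform**: w(t) = ((t−L)/τ)·exp(1−(t−L)/τ)·sin(2π(t−L)/T) for t ≥ L,
  zero before. It is identically zero before the onset L (making the
  ground-truth latency exact by construction), continuous at L, and
  biphasic with one dominant lobe of each sign. The period T is drawn
  uniformly from 8–16 ms per trace (typical MEP morphology at hand
  muscles) with τ = T/4, which puts the envelope peak at the first sine
  peak. The waveform is scaled so the noise-free post-stimulus
  peak-to-peak equals the drawn V_PP target exactly.
* **Latency structure**: each subject receives a mean onset drawn
  uniformly from 15–30 ms; traces scatter around it with SD 1.5 ms,
  truncated at ±3 SD and kept inside the 10–50 ms analysis window. The
  subject effect is on latency only — the simplest structure that makes
  leave-one-subject-out cross-validation genuinely harder than a random
  split.
* **Amplitude strata**: class drawn from (13 %, 18 %, 69 %) for low
  (20–100 µV), medium (100–200 µV), high (200–1000 µV); V_PP uniform
  within the class range.
* **Noise**: Gaussian white noise band-passed to 10–500 Hz (4th-order
  Butterworth, zero-phase) and rescaled to SD 5 µV — this puts the low-
  amplitude stratum (V_PP down to 20 µV) at a peak SNR of roughly 2, the
  deliberately hard regime. A sinusoidal baseline drift (10 µV, 1 Hz,
  random phase) models residual low-frequency wander.
* Defaults: 9 subjects, 3 kHz, epochs spanning −1000 to +100 ms.

What the generator does **not** model: motor-unit superposition and
physiological EMG spectra, amplitude–latency correlations, annotation
noise (the ground truth is the exact template onset), non-stationary
noise, stimulation-paradigm effects on waveform shape. Consequences for
interpreting the benchmark:

* Accuracies are optimistic relative to expert-annotated data, because
  there is no annotation error in the reference (~0.4–0.5 ms between real
  experts).
* Amplitude-stratified errors expose the pure SNR effect: the network
  reaches ~0.1–0.2 ms on high-amplitude epochs but ~0.5–0.7 ms on the
  low stratum, whose noise-driven onset-information floor is of that
  order (onset blur ≈ noise SD / waveform slope). On real data a shared
  annotation error masks much of this gap, so "accuracy independent of
  amplitude" is a stronger claim on synthetic data than on expert-labelled
  data — the toolkit reports the stratified MAEs and the ratio rather
  than asserting independence.

## Evaluation harnesses

* **MAE** pairs predictions and references by trace id; discarded
  estimates are excluded pairwise in single-estimator reports. Reports
  include amplitude-stratified MAEs (the overall MAE is their
  count-weighted mean) and the fractions of epochs with |error| < 0.5 and
  < 1.0 ms.
* **Multi-estimator comparisons** restrict all methods to the traces kept
  by *every* method, so each row's MAE is computed on the same n (the
  protocol that makes a discarding estimator comparable to non-discarding
  ones).
* **80/20 split**: seeded shuffle, train gets ⌊0.8 n⌋ traces.
* **Within-subject k-fold** (k = 5): per subject, seeded shuffle then
  contiguous blocks, remainder spread one per leading fold; every trace
  is validated exactly once.
* **Leave-one-subject-out**: train on all other subjects, score the
  held-out subject.
* Across folds/subjects the SD of MAE is the population SD (divisor n);
  the choice is recorded in the report metadata.
* Both CV harnesses take a pluggable `fit(train_ds) → predict` callable,
  so the same bookkeeping serves the network, the rule-based estimators
  and oracle predictors in tests.

## Numerical and scale choices

* Tolerances: preprocessing invariants are exact to 1e−12; estimator/
  oracle equivalence to 1e−9 ms; CSV round-trips to 1e−6 (≥ 6 significant
  digits written); model JSON round-trip preserves predictions to 1e−6 ms.
* Flat or too-short inputs raise descriptive errors at the stage that
  detects them; the pipeline never fabricates a latency for an epoch it
  cannot process.
* Problem sizes in `scripts/acceptance.py`: 5004 traces for the held-out
  accuracy run (9 subjects × 556), 2007 low-amplitude traces for the
  estimator comparison, 150 traces/subject for LOSO and 100/subject for
  within-subject 5-fold — sizes chosen so the whole script completes in
  about a minute on a single CPU while keeping every estimate's sampling
  error well below the effects being measured.

## Known limitations

* The network requires 3 kHz input (120 samples in 10–50 ms); other rates
  need upstream resampling.
* Training is CPU-only and single-threaded by design; it takes seconds at
  the sizes above, so GPU support is not worth its complexity here.
* The rule-based estimators follow their published operational
  descriptions; private details of the original third-party
  implementations (e.g. Signal Hunter's exact smoothing edge policy) may
  differ in ways those descriptions do not pin down.
* Reproducibility is guaranteed for fixed seed on one platform; BLAS and
  libm differences can change trained weights across platforms.
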