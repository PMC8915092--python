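# Methods

`wristhrv` validates time-domain heart-rate-variability (HRV) estimation
from wrist optical (PPG) wearables against a chest-strap reference. The
pipeline runs in five stages — simulate (or load), impute, map, compute
HRV, validate — and every stage is testable against exact ground truth
because the synthetic cohort generator produces the clean reference first.

## The data model

Wrist devices export instantaneous heart rate (bpm) on a roughly uniform
grid, with gaps where the sensor lost skin contact. After
`resample_uniform`, missingness is explicit: a series is a uniform grid of
timestamps with `NaN` at unobserved slots, so imputation operates on a
regular index. Heart rate outside a plausibility band of (20, 260) bpm is
treated as a sensor glitch and rejected on read (configurably coerced to
missing). Timestamps are epoch seconds internally; ISO-8601 is accepted on
input.

Because the series is uniformly sampled HR rather than beat detections,
inter-beat intervals are *pseudo*-intervals: IBI_ms = 60000 / HR_bpm, one
per grid slot. All interval-domain metrics inherit this convention;
pNN50 on such a series is meaningful only relative to the same convention
on the reference side. (A widely printed form of this equation,
HR = 6000/IBI, is dimensionally consistent only for centisecond
intervals; milliseconds are the HRV convention, so the constant here is
60000 and is configurable.)

## Gap imputation

Eleven univariate fillers are implemented: mean, forward/backward fill,
linear, quadratic and cubic spline, PCHIP, Akima, exponentially weighted
moving average, nearest neighbour, and k-nearest-neighbour mean. Method
choice is driven by a benchmark: gaps are injected into a complete
reference series (run lengths geometric with mean 3 slots, placed without
merging so the realised run-length distribution matches the stated one;
the two end slots are always retained as anchors), each method fills them,
and RMSE is computed over the masked slots only, so untouched observations
cannot dilute the score.

Method-specific conventions where the definitions leave room:

- EWMA fills each gap from prior observations only (forward pass), with a
  span of 5 slots; a leading gap has no history and falls back to nearest.
- `ffill` cannot fill a leading gap and `bfill` a trailing one; residual
  slots fall back to nearest so output is always complete (required
  downstream).
- kNN-mean neighbours are the k observed slots nearest in time; k is
  tuned over {1, 2, 3, 5, 7, 10} by masked-slot RMSE, ties to smallest k.
- Nearest-neighbour ties (equidistant anchors) resolve to the earlier one.
- Interpolants may overshoot on pathological gaps; filled values are
  clipped into the plausibility band.

An Augmented Dickey–Fuller test (constant regression, AIC lag selection,
via statsmodels) provides the stationarity diagnostic that motivates
interpolation over global filling: resting wrist HR series are typically
non-stationary (slow drift), so series-level statistics such as the mean
make poor fillers.

## Wrist-to-reference mapping

The systematic error of the wrist sensor is learned as a supervised
regression from time-aligned (wrist, reference) pairs. Eight families are
compared: multinomial logistic regression (integer-rounded bpm values as
categories), k-nearest neighbours, decision tree, random forest, AdaBoost,
ordinary linear regression, and two small recurrent nets (single-layer
RNN; LSTM + two sigmoid dense layers with dropout 0.2). The
sklearn-backed families use the standard estimators; the recurrent nets
are implemented in numpy with explicit backpropagation through time,
since the footprint needed here (one input feature, window 10, ~10^4
samples) does not warrant a deep-learning framework.

Protocol:

- 75/25 train/test split, stratified by subject as a chronological
  prefix/suffix per subject, so each subject's test rows form a contiguous
  segment that still supports HRV computation.
- 5-fold cross-validated grid search on negated MSE (larger is better);
  exhaustive over the declared grid, ties to the first point. Folds are
  plain shuffled k-fold within the training rows (configurable in
  principle to grouped folds; subject-boundary leakage at this stage only
  affects hyperparameter choice, not the test RMSE).
- Default grids: knn k ∈ {3,5,7,11}; tree depth ∈ {3,5,10,none}; forest
  trees ∈ {50,100,200}; AdaBoost estimators ∈ {25,50,100}; logistic C ∈
  {0.1,1}; net hidden units ∈ {8,16}. Linear regression has no grid and
  reports an empty hyperparameter set.
- Final models are refit on the full training rows and compared by test
  RMSE in bpm (the interval-vs-bpm unit ambiguity of such tables is
  resolved here in favour of bpm).

Recurrent-net details: inputs are per-subject sliding windows of 10 slots
(left-padded with the first value), min–max scaled to [0,1]; targets are
min–max normalised to [0,1] to match the sigmoid output heads and
inverse-transformed for scoring. Training is fixed at 15 epochs, batch
64, Adam with learning rate 0.1 and first-moment decay β₁ = 0.5 ("momentum
0.5" maps onto β₁ since Adam has no classical momentum). Numerical
choices that make this unusually large learning rate trainable: Adam's
second-moment decay β₂ = 0.9 (fast adaptation shrinks steps as soon as
gradients turn noisy near a minimum — with the conventional 0.999 the
parameters oscillate and the tanh layer can saturate into a constant
predictor), zero-initialised output heads (training starts from the
mid-range prediction 0.5), Glorot initialisation elsewhere, a forget-gate
bias of 1, and global gradient-norm clipping at 1. Dropout regularises
the LSTM stack only; the single-layer RNN carries none.

## Artifact correction and HRV indices

Four classical detection rules operate on the interval series, all
thresholds overridable:

- Malik: |IBI − previous accepted| > 20% of the previous accepted.
- Karlsson: deviation > 20% from the mean of the raw previous and next
  intervals (cannot flag the last interval).
- Kamath: increase > 32.5% or decrease > 24.5% versus the previous
  accepted interval.
- Acar: deviation > 20% from the mean of up to the last 9 accepted
  intervals (window shrinks near the start).

Malik, Kamath and Acar compare against previously *accepted* intervals
rather than the raw predecessor, so a premature beat followed by its
compensatory pause is flagged as a pair rather than re-normalised by its
own artifact; this convention is configurable in spirit (thresholds) and
documented because reference tools do not state theirs. The first
interval is never flagged. Accepted-anchor comparison has a failure
mode: if a spurious value is ever accepted as anchor, every subsequent
normal interval can exceed the threshold and the rest of the recording
gets flagged. A bounded-cascade guard prevents this: after
`max_consecutive_flags` (default 5) consecutive flags the next interval
is accepted unconditionally, re-synchronising the anchor while leaving
short ectopic bursts fully flagged. Flagged intervals are replaced by a
cubic spline through the accepted intervals (at least 4 required) and
marked `interpolated`; replacements are clamped into the accepted-value
range, since an unconstrained cubic overshoots between sparse anchors and
diverges when artifacts sit at the series edge (extrapolation).

Rule selection mirrors validation practice against a reference tool: each
rule's corrected per-subject index vectors (SDNN, RMSSD, pNN50) are scored
by squared Pearson correlation against the reference vectors, averaged
over the three metrics, argmax wins, ties in rule order (Malik, Karlsson,
Kamath, Acar). R² here is the squared correlation coefficient, not
1 − SSE/SST. With fewer than three subjects the score is unstable and a
warning is raised.

Time-domain indices on the corrected series: SDNN (sample SD, n−1
denominator, configurable to population SD), RMSSD, pNN50 (strictly
greater than 50 ms, denominator n−1), and the 5-minute-segment indices
SDANN (SD of segment means) and SDNN index (mean of segment SDs).
Segments are non-overlapping, delimited by cumulative elapsed interval
time; trailing partial segments are dropped (short-segment statistics are
unstable), and both segment indices are NaN with fewer than two complete
segments. HR summary statistics come from 60000/interval.

## Paired validation statistics

Per-subject HRV summaries from the wrist pipeline and the reference are
compared metric-by-metric with a paired Student t-test
(t = mean(d)/(sd(d)/√n), df = n − 1). Reported p-values are two-tailed;
the critical values printed alongside (1.833 at 95%, 2.821 at 99% for
df = 9) are one-tailed t-table entries, the convention of HRV validation
reports — both are exposed, and the accept/reject decision is driven by
the p-value at α = 0.05. Five-number boxplot summaries per group
accompany each comparison. A failure to reject is reported as computed;
whether it constitutes evidence of agreement is an interpretive question
the package does not answer (equivalence testing and Bland–Altman limits
are deliberate non-goals).

## The synthetic cohort generator

Each subject's clean reference is
HR(t) = baseline + A·sin(2πt/T) + AR(1) + trend + ε, sampled at 1 s for
900 s (a 15-minute resting protocol):

- baseline drawn from 60–90 bpm (older-adult resting range);
- A ∈ 2–5 bpm with T ∈ 10–15 s, a respiratory-sinus-arrhythmia proxy at
  resting breathing rates;
- AR(1) with coefficient 0.995 and innovation SD ≈ 0.25 bpm — a
  near-unit-root drift that, together with a 3 bpm linear trend, gives
  the series the non-stationary character an ADF test diagnoses in real
  resting recordings;
- white beat-to-beat noise ε with SD ≈ 1.2 bpm, the fast vagal component
  the slow terms cannot produce; without it pNN50 degenerates to 0 for
  every subject. Resulting ground-truth indices (SDNN ≈ 30–40 ms,
  RMSSD ≈ 20–30 ms, pNN50 a few percent) sit in the plausible range for
  resting older adults.

The wrist series is the reference degraded in order: additive bias,
Gaussian measurement noise, ectopic events (each shortens one interval by
a fraction, 0.4 by default, and lengthens the next compensatorily — the
canonical premature-beat signature, expressed in the HR domain), then
random gaps via the same injector the benchmark uses. Presets: `none`,
`mild` (bias 1 bpm, noise 1 bpm, 5% missing, ectopic rate 0.005), `heavy`
(bias 3 bpm, noise 2.5 bpm, 15% missing, ectopic rate 0.02). All
per-subject seeds derive from one master seed.

What the generator does **not** emulate: PPG waveform morphology and
motion-artifact spectra, heart-rate responses to activity or posture
change, device-specific proprietary smoothing, and real beat-detection
timing (the pseudo-IBI convention above). Passing tests therefore
demonstrate correctness of the algorithms and internal consistency of the
pipeline under controlled degradations, not field accuracy of any
particular device.

## Problem sizes and determinism

Default validation runs use 10 subjects × 900 one-second slots — the
cohort scale the generator emulates — which keeps a full 8-family mapping
evaluation around a minute on one CPU; the paired t-test calibration uses
2000 null replicates of n = 10. Every stochastic component (cohort
simulation, gap injection, fold shuffling, net initialisation and batch
order, dropout) is driven by explicit integer seeds, and a pipeline run
records a hash of its numeric outputs in the manifest so reruns are
verifiable bit-for-bit.

## Known limitations

- The recurrent nets run at the fixed, unusually aggressive optimiser
  settings described above; they train reliably with the stabilisations
  listed, but their final RMSE retains more seed-to-seed variance than
  the closed-form and tree-based families.
- Multinomial logistic regression over integer-bpm categories scales
  poorly in the number of distinct categories and is the slowest family.
- Karlsson and Acar corrections are not guaranteed idempotent (a
  replacement can shift the local context of later comparisons);
  Malik and Kamath are asserted idempotent on synthetic data.
- The imputation benchmark's RMSE is data-dependent (series shape,
  missingness fraction, gap geometry); rankings, not absolute RMSE
  values, are the stable output.
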