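# Methods

This note documents the models behind `headvel`, the parameters that
matter, the choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Rotation stimuli

A direction sweep is one half-period of a sinusoidal velocity profile: the
platform accelerates from rest to `peak_velocity` and back to rest while
turning through `2 * amplitude` degrees. The sweep duration is the closed
form `D = pi * theta / (2 V)` (theta in degrees, V in deg/s): 3.53 s for a
180-degree sweep at 80 deg/s. A full stimulus is a half-sine ramp,
`n_periods` full periods, and a half-sine ramp out — a single continuous
sinusoid spanning `(n_periods + 1)` periods — flanked by stationary
padding. Velocity is forced to exactly zero at every sweep boundary so the
direction segments partition the trajectory cleanly. The composition of
ramps and periods used in any given experiment is a protocol detail; the
generator exposes `n_periods` and `amplitude` rather than fixing one
protocol.

The behavioral stimulus families share one sweep duration (set by a
45-degree rotation at 80 deg/s, the pre-training stimulus) and differ only
in peak velocity: the non-rewarded stimulus spans 0–27 deg/s; the rewarded
peaks are 27, 37, 51, 65 and 80 deg/s for pair families 1–5. Families 1
(identical), 2 (+10 deg/s) and 5 (0–80) are pinned by the task design; the
51 and 65 deg/s intermediates were chosen once to satisfy the ">= 24 deg/s
difference" constraint and to spread the psychometric axis, and are not
revisited.

## Membrane-potential model

`vm(t) = baseline + g_dir * |velocity(t)| + visual(t) + OU(t)`.

* `g_dir` — per-direction gain, mV per deg/s. ON cells have non-negative
  gains, OFF non-positive, ON-OFF opposite signs, NONE zero. Default scale
  0.035 mV/(deg/s), per-neuron lognormal scatter (sigma 0.3).
* `OU(t)` — stationary Ornstein–Uhlenbeck noise, standard deviation
  `noise_sd` (default 2.5 mV) and correlation time `noise_tau` (default
  20 ms, a membrane-like timescale). Generated by the exact AR(1)
  discretization through a linear filter.
* `visual(t)` — for visual conditions, |velocity| low-pass filtered with a
  150-ms exponential kernel and delayed by a 60-ms latency, scaled by
  `visual_gain`. Visual responses are deliberately slower than vestibular
  ones so the two components are temporally distinct. The combined
  (vestibulo-visual) condition is the exact sum of the two components plus
  noise, giving the summation analysis a known ground truth; lesion trials
  carry no vestibular component.
* Spikes — a 2-ms triangular waveform (45 mV) inserted at upward
  crossings of `spike_threshold` with a 5-ms refractory period. This is
  sufficient to exercise spike clipping; it is not a biophysical spike
  model.

The default calibration targets the scale of awake deep-layer recordings:
with the default gain and noise, a clockwise-preferring cell driven at
80 deg/s shows a mean depolarization of ~1.8 mV across the rotation
trajectory and a mean per-trial absolute peak of ~11 mV (the peak is
dominated by noise excursions riding on the tuned response, as per-trial
peaks of real traces are). These two scales fixed the (gain, noise_sd)
pair at (0.035, 2.5); they were verified by simulation and then frozen.

What the generator does **not** emulate: biophysical conductances, spike
afterpotentials, nystagmus or eye-movement coupling, adaptation across
trials, non-stationary baselines, and recording artifacts. Passing tests
therefore demonstrate correctness of the analysis chain under the model's
assumptions (linear tuning, stationary colored noise, additive
multisensory combination), not robustness to every pathology of real
recordings.

## Response detection and classification

Baseline is the mean over the 2 s immediately preceding motion onset (the
window's placement is a convention; only its 2-s width is fixed by the
protocol). The rotation mean is taken over the union of the direction's
sweep segments, after clipping spikes: the trace inside [−2 ms, +5 ms]
around each spike peak is replaced by linear interpolation between the
window edges (the window covers the action potential and fast
after-hyperpolarization; overlapping windows are merged, edge windows
truncated). The per-direction test is a two-sided Wilcoxon signed-rank on
the per-trial (rotation, baseline) pairs — exact null for n < 25
informative pairs and no rank ties, normal approximation with tie
correction otherwise; all-zero differences yield a flagged degenerate
result with p = 1 rather than an error.

Peak amplitude is the average over trials of each trial's absolute peak
deviation from its own baseline (per-trial peaks averaged, not the peak of
the average trace). Classification: ON if at least one significant
depolarization and no significant hyperpolarization, OFF for the converse,
ON-OFF for one of each (DSI forced to 1), NONE otherwise; DSI is computed
on |delta| from baseline with Pref the direction of larger |delta|.

The learning criterion for behavior is a five-block window averaging
strictly above 80% ("performed above criterion"); a window at exactly
80.0% does not qualify.

## Circular-shuffle encoding test

Each trial is re-sampled so every kinematic bin holds exactly one vm
sample: within each monotone phase of |velocity| (rising and falling
halves of each sweep, handled separately and concatenated in temporal
order), the sample nearest in time to each bin-center crossing is taken.
Bin widths are 0.008 deg/s (velocity) and 0.007 deg/s² (acceleration).
The observed statistic is the R² of an intercept-carrying OLS fit of the
trial-averaged resampled vm on the kinematic variable — computed on the
averaged curve, not pooled points. The null draws, per iteration, an
independent uniform circular shift in [1, n−1] for every trial (the shift
law is a choice; the construction only requires temporal-structure
preservation), averages the shifted trials, and records R².

p = max(#{R²_null ≥ R²_raw}/n_iter, 1/n_iter). The floor makes the
smallest attainable p exactly 10⁻⁴ at 10,000 iterations. (The alternative
(1+#)/(1+n_iter) convention would make the minimum 1/10001 and violate the
stated floor; the floored form is used throughout.) Empirically the test
is slightly conservative on untuned cells (type-I ≈ 0.04 at alpha 0.05
over 500 null simulations), as permutation tests with a p floor are.

Runtime scales with n_iter × n_trials × n_bins; the resampling resolution
is an accuracy knob, not part of the null's validity, so the test suite
runs the calibration at 0.25 deg/s bins with 200 iterations per cell and
the floor check at 0.08 deg/s with the full 10,000 iterations.

## Naive-Bayes decoder

Profiles: per trial, the baseline-subtracted vm is averaged within each
1-deg/s |velocity| bin over 0–80 (bins a trial never visits are filled by
linear interpolation across bin centers); the sign correction
Vm⁺ = sign(V̄m)·Vm uses the mean response of the **source neuron** (mean
over its trials and velocities, sign(0) := +1), so OFF cells contribute
increasing-with-velocity statistics after the flip; each trial is then
min-max normalized to [0, 1] (a flat profile normalizes to zeros and is
flagged). Each trial is treated as an independent "cell".

The conditional P(vᵢ|velocity) is a histogram over B = 10 equal-width
response bins on [0, 1] with Laplace pseudo-count alpha = 1 (both
configurable); the estimator form is a design choice — only "estimated
from the n−1 other cells" is fixed. Leave-one-out is taken within the
currently selected subset by default (a flag switches to leave-one-out
against the full dataset); k = 1 necessarily uses the full dataset, each
trial decoded once. Decoding accumulates log-probabilities over the 80
candidate bins and returns the argmax bin center, ties broken toward the
lowest velocity (numpy's first-maximum convention, fixed and documented).
The error is the mean absolute deviation between the 80 predictions and
the bin centers k − ½; a uniform-random decoder scores (80²−1)/(3·80)
≈ 26.66 deg/s.

The sweep implementation vectorizes the leave-one-out counts
(subtracting each observer's own histogram contribution in closed form),
and is verified in tests against the granular fit-then-decode path and a
direct product-of-probabilities oracle.

## Range separation

Per iteration, one random k-subset decodes every 1-deg/s bin of both
ranges (27 estimates for 0–27 deg/s; 348 iterations give the 9,396-
estimate geometry). An estimate is erroneous for the slow range iff it
exceeds 27 deg/s (strictly; estimates below 0 are impossible by
construction). The separation index is the area above the cumulative
distribution of the fast-range estimates beyond 27 deg/s, normalized by
the 53-deg/s width of that region so the index lies in [0, 1] — the
normalization makes values comparable only within this package, so
absolute index values are not matched against external curves. The
per-iteration Fisher exact test uses the 2×2 outside/inside table of the
two matched estimate sets. Index versus k is summarized by the saturating
double exponential a₁(1−e^(−k/τ₁)) + a₂(1−e^(−k/τ₂)) (a raw sum of
decaying exponentials is available via flag).

## Multisensory comparison

All correlograms are computed on mean-subtracted series with lags up to
±25% of the window and normalized by the geometric mean of the
full-window sums of squares, so a self-comparison peaks at exactly 1 at
lag 0. The within-cell normalizer is the odd/even-trial autocorrelation
peak of the combined condition; candidate coefficients (sum, visual-only,
vestibular-only) are peak cross-correlations divided by that normalizer
and may exceed 1 when the candidate matches the combined average better
than the noisy trial-splits match each other. The arithmetic sum
references each unisensory average to its own pre-stimulus baseline and
restores the mean of the two baselines as the common offset, which keeps
the operation commutative. Baseline-subtracted averages are the default;
raw averages are a parameter away.

## Imaging

De-rotation rotates each frame by the negative of its encoder angle about
the rotation center with bilinear interpolation, fills revealed corners
with the frame median, and resizes onto a 200×200 canvas; frames with a
missing angle are dropped with a log entry. Encoder angles are quantized
to 0.05 degrees, the precision of the rotary-encoder feedback. ΔF/F uses
the sweep-mean fluorescence as baseline. Transient detection
median-filters the ΔF/F trace (width 7 frames), differentiates, and
thresholds at mean + k·SD of the derivative with k = 1.35 (midpoint of
the conventional 1.2–1.5 range); the SD is computed per trace on the full
derivative including transients (a robust MAD-based option exists).
Event-rate comparisons require matched stationary/rotation epoch
durations and classify ROIs as increase/decrease/none by signed-rank at
alpha 0.05.

## Statistics

Fisher exact tests are two-sided by the probability-mass rule (sum of all
tables with the observed margins whose probability does not exceed the
observed one); chi-square on 2×2 tables is Pearson's without continuity
correction, df = 1. Both are cross-checked in the test suite against
brute-force enumeration; the Wilcoxon wrapper is checked against
exhaustive sign-assignment enumeration for n ≤ 10.

## Problem sizes in the test and acceptance suites

Simulated populations use the full 348-trial / 8-neuron geometry at a
1-kHz membrane-potential grid (the tuning model is instantaneous, so the
grid sets only the noise-averaging resolution). Network sweeps in tests
use 30–50 repeats per k; separation analyses 40–60 iterations; the
shuffle-test calibration 500 null cells at 200 iterations each; the
multisensory ranking 25–30 seeded constructions. These sizes keep the
statistical conclusions (orderings, calibration bands) stable across
seeds while the full-scale settings (348 repeats, 10,000 iterations)
remain the defaults of the corresponding functions.

## Known limitations

* The decoder's absolute error values depend on the generator's
  signal-to-noise ratio; only orderings and bounds are asserted.
* The circular-shuffle null assumes approximate circular stationarity of
  the noise; strongly non-stationary baselines would distort the floor.
* The separation index normalization is package-internal (see above).
* De-rotation accuracy is quoted away from frame edges; corners revealed
  by rotation carry fill values and should be masked downstream.
* The pipeline's multisensory stage compares trial averages of one
  simulated cell; population-level inference across cells is left to the
  library functions it wraps.
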