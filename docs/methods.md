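# Methods

This note documents the models, parameters and experiment designs behind
`edaffect`: what each stage assumes, which defaults matter and why, and
what the synthetic experiments do and do not establish.

## Signal model and conditioning

A GSR sensor reports skin resistance R (Ω) with a timestamp in ms. Skin
conductance is the physical reciprocal, expressed in microsiemens:
EDA = 10⁶ / R. Device timestamps may be slightly irregular; conversion
linearly interpolates onto a uniform grid at the session's nominal
acquisition rate (default 8 Hz; the wearable's true rate is a free
parameter of `RawSession` and of the generator).

Downsampling to 2 Hz uses block averaging rather than decimation: each
output sample is the mean of its source block, which anti-aliases while
reducing rate. When the input rate is not an integer multiple of 2 Hz
the signal is first linearly resampled onto the nearest integer-multiple
grid.

Artifact removal is a median filter, default window 5 samples (2.5 s at
2 Hz), reflected padding. The median rejects isolated motion spikes
without smearing them into neighbours. Two side effects matter
downstream: a noisy monotone ramp becomes a slight staircase (flat steps
followed by double-height slopes), and the endpoints of a ramp are
eroded by roughly half the window (~0.5 s per side). Both interact with
event detection; see below.

## Tonic–phasic decomposition and SCR detection

The tonic component (skin conductance level) is a centred moving average
over a 10 s window, reflect-padded; the phasic component is the residual,
so tonic + phasic reconstructs the input exactly. A moving average was
chosen over convex-optimisation decompositions because it is linear,
transparent, and exactly testable (the moving average of a line is the
line; a constant signal is all tonic). The window is forced to an odd
sample count so the average is truly centred. The decomposition is
pluggable: anything producing a `PhasicDecomposition` can feed the
detector.

An SCR event is a maximal run of consecutive first-difference slopes of
the phasic trace that all exceed 0.01 µS/s in magnitude with constant
sign and persist for at least 3 s. Rising runs are peaks, falling runs
offsets. `end_index` is the index of the run's final sample, so
`duration = (end_index − start_index) / rate` is the time between the
run's endpoints; amplitude is the absolute phasic change across the run,
which is therefore bounded below by slope_threshold × min_duration.
Slopes are raw first differences of the (median-filtered) phasic trace;
no derivative smoothing is applied, keeping the detector's semantics
identical to the brute-force run enumerator used as its test oracle.

Detection-margin accounting, measured on noiseless synthetic kernels: the
median filter erodes a ramp's detected run by ~0.5 s, and subtracting the
10 s moving-average tonic cuts the apparent slope of a 4 s rise by
~25–35%. A kernel rising for exactly 3.5 s therefore yields a detected
run of 3.0 s — zero margin against the 3 s rule — and kernels whose rise
slope sits at the detector's sensitivity floor (≈3× the slope threshold)
are recovered only ~80–93% of the time under 0.005 µS sensor noise,
because a single noise-dip in the slope run splits it below the duration
minimum. Robust recovery (the ≥95% demonstrated in the tests) requires
kernels that clear both margins, which the generator's default
high-arousal kernel (0.3 µS over a 4.0 s rise, 7.5× the slope floor)
does. Low-arousal kernels (0.1 µS over 3.3 s, 1.01× the 3×-threshold
floor) are deliberately marginal: small SCRs are genuinely hard to
detect, and the classifiers separate arousal levels through event rate
and amplitude statistics rather than perfect recovery.

## Features

Nine statistical descriptors are computed on the conditioned 2 Hz trace:
mean, median, population standard deviation, max, min, excess (Fisher)
kurtosis and standardized skewness (both defined as 0 for zero-variance
traces), area under the curve per second (trapezoidal integral divided
by duration), and the median of the Welch power-spectral-density
estimate (64-sample segments, 50% overlap). Six event descriptors follow
from detection: mean/max peak amplitude, mean/max offset amplitude
(0 when no such event), and peaks/offsets per second of segment
duration. Event amplitudes are reported in µS by default; an
`amplitude_units="seconds"` switch summarises event durations instead,
for pipelines that read an event's size as how long it lasted rather
than how far the conductance moved.

Normalization is per-column min–max to [0, 1]; a constant column maps to
all zeros. The fitted extrema are retained so streaming windows are
transformed with the training-time scaler. When `train_and_tune`
receives an *unnormalized* table it instead fits the scaler inside each
training fold (leakage-free); passing a pre-normalized table reproduces
the simpler whole-dataset-scaling convention. Both paths are supported
because whole-dataset scaling is common in small-sample affective
computing studies despite its mild optimism.

## Feature selection

Chi-square (on the non-negative normalized table), one-way ANOVA F, and
a nearest-neighbour mutual-information estimate (seeded) each order the
15 features for a target — the 4-class label or one quadrant's
one-vs-rest indicator. The orders are combined by Borda rank-sum voting:
a feature's score is the sum of its 1-based positions, lower is better;
ties break by the ANOVA-F position, then name. Borda was chosen as the
simplest order-based aggregation; scores on incommensurable scales are
never mixed directly.

## Models and evaluation

Five algorithm families are searched: k-nearest neighbours, random
forest, multi-layer perceptron, linear SVC, gradient boosting. The
linear SVC is wrapped so a logistic squash of its decision scores
provides probabilities, keeping the four-pair output contract uniform.
Randomized search draws hyperparameter configurations per algorithm
(library defaults: 50 draws, capped by the size of the discrete grid)
crossed with feature-count prefixes {5, 8, 10, 12, 15} of the target's
voted ranking; selection maximizes mean F1 under repeated stratified
5-fold cross-validation (default 10 repeats). The binary subproblems
have 25% positive prevalence, so the RF and LSVC search spaces include
`class_weight="balanced"`; this matters for one-vs-rest models and is a
no-op for the class-balanced 4-class problem. All randomness flows from
one seed; identical seeds give identical selections and metrics.

Binary metrics use the positive-class convention with zero-division → 0;
4-class metrics are support-weighted. Predictions are four
(flag, probability) pairs in Happy, Sad, Aggressive, Relaxed order with
flag ⇔ probability ≥ threshold (default 0.5).

## Synthetic experiment generator

A segment is baseline + tonic random walk (scale `tonic_drift_sd`
µS/√s) + Poisson-arriving SCR kernels (linear rise `scr_rise`,
exponential decay `scr_decay`, log-normal amplitude) + white Gaussian
sensor noise, clipped to stay positive, converted to resistance and
rounded to the device's 6-significant-digit printed precision. Ground-
truth onsets are returned alongside, so detector recovery is scorable.

Default per-quadrant profiles encode the arousal axis: high-arousal
quadrants (Happy, Aggressive) get 6 SCR/min at 0.3 µS median amplitude,
low-arousal (Sad, Relaxed) 1.5/min at 0.1 µS. Valence is injected only
through mild tonic-baseline shifts (Sad 2, Relaxed 4, Happy 6,
Aggressive 10 µS) — a modelling convenience for class separability, not
a physiological claim. The full experiment default emulates the study
protocol: 32 participants, one session each of nine songs (one
relaxation + two per quadrant, 15 s pauses, 260 s songs → 41 min), with
7 sessions corrupted by cycling through four modes (truncation, clock
scramble, out-of-range burst, acquisition gap) chosen so every
validation failure code is exercised. Validation then segmentation of
the default corpus yields exactly 25 valid sessions × 8 segments = 200
labeled segments, 50 per quadrant.

A second profile family, `contrast_profiles(strength)`, supports
architecture experiments: each quadrant departs from a common physiology
along its own axis (Happy by SCR rate, Aggressive by SCR amplitude, Sad
by tonic level, Relaxed by tonic variability), with `strength` grading
the class overlap from separable toward chance.

**What the generator does not model:** real inter-subject variability,
electrode drift and detachment, motion artifacts with temporal
structure, overlapping-SCR shape distortion, or any empirically
validated link between music-induced emotion and EDA statistics. Tests
passing on synthetic corpora demonstrate that the pipeline's mechanics
are correct and that its architecture comparisons behave as designed —
not that the classifiers would reach any particular accuracy on real
recordings.

## Experiment designs used in the tests

Problem sizes are deliberately desk-scale. The architecture comparison
uses 20 replicate corpora of 12 segments per quadrant (60 s each, 8 Hz)
at graded contrast strengths {0.45, 0.35, 0.3, 0.25}, a compact search
(RF/KNN/LSVC, prefixes {5, 15}, 3 draws, single 5-fold CV), and compares
the mean selected per-quadrant binary F1 with the selected 4-class
model's per-class F1 on the same fold protocol. In this hard regime
(binary F1 ≈ 0.6–0.8) the binary architecture consistently wins — the
one-vs-rest subproblems can exploit class weighting and per-quadrant
feature/algorithm choices that the single 4-class model cannot — while
on easy (default-profile) corpora both architectures saturate and the
comparison is uninformative. Signal-free corpora (all quadrants drawn
from one profile) drive the selected binary F1 into the chance band for
a 25%-prevalence positive class. Detector recovery uses 50 seeded
120 s segments at 1 SCR/min with the default high-arousal kernel and
0.005 µS noise, matching detected peaks to injected rises by time
overlap.

## Numerical conventions and degenerate inputs

Zero-variance traces: Std = 0, Skewness = Kurtosis = 0. Empty event
sets: amplitude features 0, rates 0. Constant feature columns normalize
to 0 and rank last (score 0) in all three tests. Infinite ANOVA-F
(zero within-class variance) is mapped to the largest float so it ranks
first deterministically. Ranking ties break by score descending, then
feature name. Raw-log round-trips are exact because the generator and
writer share the 6-significant-digit resistance convention and
timestamps are written as integers when integral. Validation never
raises on bad data — it reports reason codes (TRUNCATED,
NONMONOTONE_TIME, OUT_OF_RANGE, GAP) and is a pure function of its
inputs.

## Known limitations

- The tonic moving average leaks a fraction of each SCR into the tonic
  estimate, attenuating phasic slopes; a deconvolution- or
  convex-optimisation-based decomposition would sharpen detection but is
  out of scope.
- Events at the detector's sensitivity floor (slope ≈ 3× threshold) are
  recovered at only ~80–93% under realistic noise; see the margin
  accounting above.
- Streaming windows re-run the whole chain per window; tonic state is
  not carried across windows, so a 30 s window's tonic estimate is
  noisier than the offline one.
- The per-window feature distribution differs from the per-song training
  distribution (shorter windows quantize event rates); models trained on
  song segments still transfer on synthetic data, but this is a known
  distribution shift.
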