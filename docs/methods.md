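# Methods

## Problem

Body mass index (BMI = weight in kg / height in m²) leaves a signature in
gait: heavier people tend to move with larger acceleration amplitudes and a
slightly different cadence. `motionbmi` estimates a person's BMI from the
six-channel inertial stream of a smartphone carried in a pocket (tri-axial
accelerometer + tri-axial gyroscope), with no anthropometric input. The
pipeline is: resample → fixed-length windowing → per-window normalization →
entropy-based window selection → regression (hybrid CNN-LSTM or classical
feature-based learners) → leave-one-subject-out (LOSO) evaluation.

## Motion entropy

Motion entropy (MEn) extends sample entropy (SampEn) to the joint
accelerometer/gyroscope stream. For a window of length `w`:

1. Each tri-axial sample is collapsed to its vector magnitude, giving two
   non-negative series `Acc_i`, `Gyro_i` (orientation-robust by
   construction).
2. Templates are runs of `ξ` consecutive magnitude samples; the distance
   between two templates is the Chebyshev (maximum absolute difference)
   distance, computed separately per sensor.
3. A template pair *matches* within tolerances `(r_acc, r_gyro)`. `B^ξ` is
   the average per-template fraction of matching partners (self-pairs
   excluded), and

       MEn = −ln( B^{ξ+1} / B^ξ ).

Low MEn means a highly regular signal (e.g. near-periodic, low-noise gait);
high MEn an irregular one. When no pair matches at length `ξ+1` the
conditional probability is zero and MEn is reported as `+inf` with a
degeneracy flag.

Two definitional choices are exposed because the defining sums admit two
readings each:

* `match_mode` — `literal_average` (default) scores a pair as the *mean* of
  the two per-sensor match indicators, so a pair matching on one sensor only
  contributes 1/2; `joint` requires both sensors to match (the natural
  multichannel AND). Both are implemented and oracle-tested.
* `normalization` — `sampen_consistent` (default) evaluates both template
  lengths over the pair set valid at length `ξ+1`. This guarantees
  `B^{ξ+1} ≤ B^ξ`, hence MEn ≥ 0, matching the SampEn tradition.
  `strict_literal` instead gives each length its own index range
  (`w−ξ+1` templates at length `ξ`), which can produce small negative
  values; it is kept for fidelity to the plain reading of the defining
  sums.

Defaults: `ξ = 2` (the standard SampEn template length — no other value is
canonical for this statistic), tolerance multiplier `ψ = 0.05` from the
conventional grid {0.01, 0.05, 0.1}. Tolerances are calibrated as
`r = ψ × mean per-window standard deviation of the magnitude series`,
computed on the **training pool only** so filtering never sees test data.
Because `r` scales with the signal's own dispersion, MEn is invariant to
the units the accelerometer is logged in (g vs m/s²).

## Entropy-based window filtering

Training windows are ranked by MEn and the `floor(θN)` lowest and
`floor(θN)` highest are discarded (`both_tails`, default), retaining the
central mass: the intuition is that the most mechanical windows (standing
still, resonant artifacts) and the most chaotic ones (pocket fumbling,
sensor noise) both carry little BMI information. `θ = 0` disables
filtering; `θ = 0.25` keeps roughly half the pool. Single-tail modes are
provided for sensitivity analysis.

Ranking uses a stable sort, so ties resolve in input order — this
rank-based trimming retains exactly `N − 2·floor(θN)` windows for tie-free
values, and the kept windows are exactly those inside the empirical
`[θ, 1−θ]` quantile band up to ±1 window at the boundary. Windows with
infinite MEn count as maximally complex and are always removed when
`θ > 0`. Filtering is applied to training windows only (the held-out
subject's windows are all evaluated), and it is label-blind by
construction.

## Front-end conventions

* **Resampling**: all channels are linearly interpolated onto a uniform
  grid spanning the original time range, default 90 Hz, so that the default
  window `w = 90` spans ~1 s of gait (about two strides when jogging).
* **Windowing**: step `θ_step = 45` (half a window, 50% overlap). The
  window count is the literal `L = floor((T − w)/step)`; note this discards
  one trailing fully-valid window when `T − w` is an exact multiple of the
  step. We keep the formula for comparability and document the off-by-one
  against the "all valid starts" convention; the property tests pin it.
* **Normalization**: per-window, per-channel z-score (default). A
  constant channel maps to zeros. Min-max to [0, 1] is available
  (constant channels map to 0.5). Each window carries its subject's single
  BMI label; BMI is assumed constant within a recording.

## The hybrid CNN-LSTM

Channels are split into an accelerometer branch and a gyroscope branch.
Each branch applies three blocks of 2-D convolution → ReLU → batch
normalization (momentum 0.99, ε = 0.001) → max pooling. Kernels are
*rectangular*, running along time within the 3-row space axis (defaults
1×9, 1×7, 1×5 with 1×2 pools), so the time axis shrinks while the space
axis survives. After the conv stack, channel and space axes are flattened
per time step — deliberately *not* the time axis, which the stacked LSTM
then consumes as its sequence dimension (flattening time away would leave
the recurrence nothing to do). The branch features are concatenated per
time step before the LSTM. A dense head with dropout and L2 weight decay
ends in one linear unit; the loss is mean squared error on standardized
labels (the standardization constants are stored with the fitted model and
undone at prediction time).

Training defaults follow the conventional grid-search optima for this
architecture family: Adam, learning rate 0.001, 200 epochs, batch 20,
dropout 0.5, L2 = 1e-4 (the decay strength itself is this package's
choice; it applies to weight matrices, not biases or batch-norm
parameters). The full grid (`grid_search`) is exhaustive with
deterministic tie-breaking by grid order.

The network is implemented directly on numpy (`motionbmi.nn`): explicit
forward/backward passes for convolution (im2col + BLAS matmuls),
batch-norm, max-pooling, LSTM (gates i, f, o, g; forget-gate bias 1) and
dense layers, with Adam/RMSprop/SGD optimizers. Arithmetic is float32; all
randomness (He/Glorot-style init, shuffling, dropout masks) flows through
one seeded generator, so training is bit-reproducible for a fixed seed and
thread count. Batch normalization uses running statistics at inference and
dropout is inactive, so prediction is deterministic and batch-size
invariant (to float32 round-off, ~1e-5).

### Desk profile

`ModelConfig.desk_profile()` is the configuration used by the test suite
and the acceptance script: feature maps (8, 16, 16), LSTM (32,), dense
(32,), dropout 0.2, Adam at 0.003, 12 epochs, batch 64. These sizes were
chosen so a full 24-fold LOSO run of the deep model completes in minutes
on one CPU core while still clearly beating the mean predictor on the
synthetic cohort; the paper-scale defaults remain available via
`ModelConfig()`.

## Classical baselines

Each window is summarized by 43 features on the three raw accelerometer
axes (z-scored data would destroy the amplitude information): per-axis
mean, standard deviation, and mean absolute deviation; mean resultant
acceleration; per-axis mean time between peaks (local maxima above the
axis mean, ≥ 0.25 s apart; windows with < 2 peaks report the window
duration); and a per-axis 10-bin equal-width value histogram normalized to
sum to 1. The bin count and peak rule are configurable since no single
convention is canonical. Baseline learners are scikit-learn regressors —
k-nearest-neighbour (k = 5), RBF support-vector regression (standardized
features), and a decision tree — plus a train-mean straw man.

## Evaluation protocol

LOSO: one fold per subject, ordered by subject id; fold `k` trains on all
other subjects' windows and tests on every window of subject `k`.
Per-fold MAE and RMSE are aggregated as the unweighted mean ± sd across
folds (window-weighted pooling would over-represent long recordings). The
per-category table groups pooled test windows by the true WHO band
(half-open intervals with inclusive lower bounds: [18.5, 25) normal
weight, [25, 30) pre-obesity, …) and reports per-band MAE plus *category
accuracy* — the fraction of windows whose predicted BMI lands in the true
band, our operationalization of band-level accuracy for a regression
output. Every fold's seed derives deterministically from the experiment
seed and the fold id, and everything fitted (filter tolerances, filter
quantiles, the regressor) sees training windows only; the perturbation
tests pin this.

## Synthetic cohort generator

`CohortSpec`/`generate_cohort` emulate the *statistical* structure of
pocket-worn gait recordings, not biomechanics: per subject, each
accelerometer axis is a static gravity/orientation offset plus a 3-harmonic
series at multiples of the subject's step frequency with subject-specific
random phases and Gaussian sensor noise; gyroscope axes are phase-shifted,
rescaled versions with 2× noise. BMI couples linearly (around a reference
BMI of 22) to amplitude (`1 + 0.04·(BMI−22)` by default) and cadence
(`2.5 − 0.02·(BMI−22)` Hz, a jogging-range base rate). Defaults: 24
subjects (a realistic cohort size for this kind of study), 60 s at 90 Hz,
noise sd 0.05 g, and a WHO-band mixture dominated by normal-weight (50%)
and pre-obesity (30%) subjects, mirroring the imbalance of young-adult
cohorts so the sparse-category code paths are exercised.

`CohortSpec.strong_signal()` raises both couplings (amplitude slope 0.08,
cadence slope −0.04 Hz per BMI unit) and lowers noise to 0.02. This is the
regime for end-to-end recovery demonstrations: per-window z-scoring erases
absolute amplitude, so the deep model must read cadence and waveform SNR,
while the raw-feature baselines read amplitude directly.

What passing tests on this generator do **not** show: robustness to real
gait variability (orientation changes mid-recording, activity transitions,
inter-stride irregularity, device heterogeneity). They do show that the
statistic, the filter, the learners and the protocol are internally
correct and that the pipeline recovers an encoded BMI signal end to end.

## Numerical choices and degenerate inputs

* Constant channels: z-score → zeros; min-max → 0.5; constant magnitude
  series calibrate to zero tolerance with a warning.
* MEn with zero matches at `ξ+1` (or `ξ`): `+inf` sentinel, flagged, upper
  tail under filtering.
* Filter ties: stable rank-based trimming (input order preserved); 1000
  identical values at θ = 0.1 retain 800 by this rule.
* Batches with a single sample are skipped during training (batch-norm
  needs ≥ 2 samples); label standardization guards against zero variance.
* Divergent training (non-finite loss) aborts with a diagnostic rather
  than returning garbage; in a grid search such candidates lose.
* Window count/step/width validation errors are explicit; `w > T` yields
  an empty window list by documented convention.

## Known limitations

* The MEn pairwise-distance computation is O(w²) per window — fine for
  w ≈ 90, not intended for minutes-long templates.
* The numpy network targets clarity and reproducibility over raw speed;
  paper-scale training (200 epochs, feature maps (32, 64, 64)) is feasible
  but slow on one core.
* Real-dataset adapters ingest a generic CSV layout; public-dataset
  column layouts vary by release and may need light renaming on ingest.
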