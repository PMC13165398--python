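# Methods

This note documents the models, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## Pose features

Each frame carries 6 keypoints (snout, midbody, endbody, tail, fan,
sidebody) in tank coordinates (origin bottom-left, feeding side aligned).
The 57-dimensional feature vector is built from 39 base features — 10
coordinates (5 body keypoints), 5 filtered velocities, snout acceleration,
snout dispersion, normalized bounding area, normalized body length,
tail–fan proportion, 6 visibility counts, snout–wall distance, heading
angle, α₁..₃ and their sum, θ₁..₃, the heading·velocity dot product,
reversal magnitude and binary, and the sleep flag — expanded by a 10-frame
rolling mean for all 39 and a rolling standard deviation for the 18
kinematic/shape features (5 velocities, acceleration, dispersion, bounding
area, body length, tail–fan proportion, 4 α's, 3 θ's, dot product). The
exact mean/std allocation is a single table in `assemble_features`, so it
can be swapped without touching any downstream code.

Numerical choices:

* **Position filter.** Velocities difference low-pass-filtered positions.
  The default is a 5-tap causal moving average (`b = [0.2]*5, a = [1]`),
  the simplest linear low-pass; coefficients are config. The filter state
  is initialized at the first sample (`lfilter_zi`) so the startup
  transient does not appear as a spurious velocity at recording start.
  Velocities use timestamps, not frame counts, so dropped frames do not
  distort speeds.
* **Dispersion.** The per-frame area of the circle whose diameter is the
  diagonal of the axis-aligned bounding box of snout positions over the
  trailing 2-s (40-frame) window: area = π(Δx² + Δy²)/4. This is computed
  from the window's coordinate extremes and upper-bounds the exact minimum
  enclosing circle (an exact Welzl implementation ships as a test oracle
  only). Trailing windows are truncated at recording start rather than
  dropped.
* **Sleep.** Frames with dispersion < 50 (same units as the area) are
  inactive; maximal inactive runs lasting ≥ 60 s are sleep in full.
  Missing dispersion breaks a run. The default keypoint jitter in the
  simulator (0.5 px) keeps resting-frame dispersion far below this
  threshold, so simulated rest scores as sleep once it exceeds a minute.
* **Angles.** α_k are interior angles at the middle keypoint of each
  consecutive body triple, in [0, π]. θ_k compare the heading with the
  local body tangent (central difference along the chain); the sign is
  positive when the heading is rotated counterclockwise of the rear
  tangent, so a body on a left-turning arc scores positive and mirror
  reflection flips the sign.
* **Missing keypoints.** Features needing an invisible keypoint are
  missing for that frame; rolling statistics require at least half the
  window present. Day-level normalizations (bounding area, body length)
  use the calendar recording day; a degenerate zero-mean day skips
  normalization with a warning.
* **PCA.** Features are z-scored (constant columns dropped with a
  warning and recorded on the result), reduced to 15 components, and the
  scores smoothed with a 10-frame moving average before HMM fitting.

## Syllable HMM and stochastic EM

A K-state Gaussian HMM with full covariances models the smoothed PC
sequence; each state is a behavioral syllable. Forward–backward is exact
and implemented twice — per-frame scaling (default) and pure log-space —
which agree to ~1e-8 and are cross-checked against exhaustive path
enumeration on toys in the tests.

Stochastic EM cuts the recording into contiguous batches of B frames.
Each update computes the batch's expected sufficient statistics (initial
and transition counts, responsibilities, first and second moments) and
blends them into a running estimate, `stats ← (1−ρ_t)·stats + ρ_t·batch`,
then re-derives parameters. Blending in sufficient-statistic space keeps
transition rows stochastic and covariances PSD by construction. The step
size is ρ_t = (t+2)^(−0.6) with ρ₁ = 1 (Robbins–Monro compliant:
decay ∈ (0.5, 1]); both decay and a constant-ρ override are config. With
a single batch and constant ρ = 1 the iteration is algebraically
full-batch Baum–Welch, which the tests assert to 1e-12. Peak memory is
O(BK²), independent of total frames.

Other choices: k-means initialization on a ≤100k-frame subsample with
shared diagonal covariance and a sticky (0.9 self-weight) transition
prior; covariance ridge 1e-6; a state whose expected count falls below 1
in a batch has its covariance reset to the global data covariance (logged).
Decoding defaults to the per-frame posterior mode (streaming-friendly);
Viterbi is available. The number of states is selected as the smallest K
whose held-out per-frame log likelihood is within a tolerance (default
0.02 nats) of the grid maximum. The full-scale default is K = 100;
tests and the demonstration pipeline use small K.

## Behaviorome tensor decomposition

Usage counts are binned at 10-minute resolution (12,000 frames per bin at
20 fps, 144 bins/day), min-max scaled per syllable over the whole dataset
(empirical minimum by default; a flag forces 0), and factored by
non-negative CP. The solver is HALS (hierarchical alternating least
squares) with 5 random restarts, 500 max iterations, and 1e-7 relative
tolerance. Masked fits (for cross-validation) impute held-out entries
with the current reconstruction between sweeps, which minimizes squared
error over observed entries only; the tests verify that perturbing
held-out entries leaves the factors unchanged. Components follow the
convention: unit-norm time and syllable factor columns, scale absorbed
into the age factors, components ordered by contribution.

Rank selection holds out 50% of (time-bin, animal-day) pairs across all
syllables, fits on the rest (warm-starting each rank from the previous
one so training error is non-increasing), and reports the normalized
error ‖X − X̂‖²/‖X‖² on both sets. The selected rank is the point of
marginal returns: the smallest R whose successor improves test error by
less than 10% of the error at R. A relative (not absolute) threshold is
used because the error scale depends on the noise floor. The full-scale
default rank is 45; tests use small ranks.

## Clocks, forecasts, survival

The behavioral clock is a random-forest regressor from one day's age
factors to age, evaluated leave-one-fish-out: all of an animal's days are
held out together, so no within-animal correlation leaks into training
(the result object records each fold's training animals, and the tests
assert the exclusion structurally). Reported: pooled Pearson R over all
held-out (true, estimated) pairs, per-age median absolute error, and
mean-decrease-in-impurity importances from a model fit to all animals.
The aging rate is each animal's least-squares slope of estimated versus
true age; groups are compared by Mann–Whitney U.

Lifespan forecasting trains an age-fixed random-forest classifier per
prediction age on the mean age factors over the window
(prediction_age − 5 d, prediction_age]; days without recordings are
simply absent from the mean (no imputation). Long-lived means lifespan
≥ 200 d (a lifespan of exactly 200 is long-lived); animals > 300 d are
excluded as extreme agers, as are animals dead before the prediction age
or with no recorded day in the window. Features are z-scored with
training-fold statistics, so the reported accuracy and ROC AUC are
invariant to feature scaling. Predicted groups are compared on true
lifespan with Kaplan–Meier curves and a log-rank test (removal before
natural death is right-censoring). Differential usage tests each factor
at each age with a two-sided Mann–Whitney U, Bonferroni-corrected within
the age (m = number of factors at that age, matching the per-age testing
loop).

## Divergences, change points, life stages

Each day is a 200-element vector (for 100 syllables): frames per syllable
during the light period, then during the dark period. Divergences use a
pseudocount of 1 frame per cell before normalization — raw usage would
give infinite divergence whenever a syllable is unused on one day — and
the normalized vectors are compared with symmetrized KL,
½KL(p‖q) + ½KL(q‖p). Gaussian emissions use the closed form. Day × day
matrices are computed with a vectorized cross-entropy identity and match
the scalar definition to 1e-10 in the tests.

Change-point detection Gaussian-smooths the daily usage series along age
(σ = 1 day), z-scores per dimension, and minimizes within-segment
RBF-kernel scatter plus a per-change penalty c·ln(L), L = recorded days,
via exact dynamic programming over O(L²) segment costs (2-D prefix sums
over the Gram matrix; minimum segment 2 days). The kernel bandwidth is
the median heuristic. **Penalty calibration:** because the RBF kernel is
bounded by 1, the scatter reduction from a true change is at most
~2·n₁·n₂/n (n₁, n₂ the flanking segment lengths), so the penalty must
stay well below the shorter flanking segment for end-of-life transitions
to remain detectable; c = 1 (penalty ≈ 5 for a 150-day record) recovers
≥ 90% of true transitions within ±2 days on well-separated synthetic
cohorts with < 2% spurious detections, and the change-point count is
monotone non-increasing in c. Transitions closer to a series end than the
±2-day tolerance are information-theoretically undetectable and account
for most residual misses.

The life-stage model Gaussian-smooths (σ = 1 day) and z-scores the age
factors, then fits a full-covariance Gaussian HMM (k-means init, 20 EM
iterations — diagonal covariance is a config option) with one observation
sequence per animal; 6 states by default, with held-out log probability
over a K grid available for selection. Stages are relabeled by the mean
age of their member days so ids progress forward. Summaries: empirical
day-to-day transition frequencies including self-transitions (a jump
matrix conditioned on change is available since self-transitions dominate
by construction), bout durations in days, per-stage median 10-min-binned
usage profiles, and pairwise emission divergences.

## Synthetic data: what it emulates, what it does not

The generator reproduces the *statistical skeleton* of lifelong
recordings: 20 fps kinematics of a 6-keypoint body driven by distinct
behavioral modes; isotropic Gaussian keypoint jitter (0.5 px default,
small against the sleep threshold); a rarely visible sidebody keypoint to
exercise missing-data paths; a 12/12 photoperiod with seven Gaussian
feeding-activity peaks at fixed times in the light period; bimodal
lifespans (truncated normals, long mean 250 d / sd 30, short mean 150 d /
sd 25, truncated at 30 d, mixed 50/50); forward-only life stages with
shifted-geometric dwell times (5-day minimum dwell by default, mean 40 d,
reflecting long stretches of stable behavior); per-stage circadian usage
templates in which rest weight grows with stage and each stage up-weights
a signature syllable block; and group differences in day-time inactivity
and feeding-peak amplitude for short-lived animals. Per-bin syllable
counts are multinomial draws from the stage template, so every bin's
counts sum exactly to frames-per-bin.

It does **not** emulate: realistic swim hydrodynamics, autocorrelated or
heavy-tailed tracker error (jitter is i.i.d.; the empirical error
distribution of keypoint trackers is not publicly characterized), video
appearance, within-day behavioral sequencing beyond the scripted modes,
or gradual within-stage drift. Passing tests therefore demonstrate that
the estimators recover the structures they target when those structures
are present at realistic scale — not that real recordings contain only
those structures.

## Problem sizes

The demonstration pipeline and test suite run at desk scale by design:
cohorts of 8–20 animals, 10–20 syllables, 24–48 bins/day with recording
days strided, HMMs with 2–4 states on 10³–10⁵ frames, tensors of order
10⁴–10⁶ entries. The estimators themselves are scale-free (stochastic EM
is explicitly memory-bounded; the CP solver and kernel DP are polynomial
in their inputs), and full-scale defaults (100 syllables, 144 bins, rank
45, 6 stages) are the package defaults wherever a size is a modeling
choice rather than a test harness choice.

## Known limitations

* The 57-feature mean/std allocation and the velocity filter coefficients
  are config-backed conventions, not uniquely determined by the feature
  definitions; swapping them changes the feature space but not the
  pipeline contracts.
* Stochastic EM converges to a local optimum; k-means initialization and
  restarts mitigate but do not eliminate initialization sensitivity.
* The change-point penalty trades recovery against spurious detections;
  transitions within ~2 days of a series end are not detectable at the
  stated tolerance.
* The life-stage HMM assumes Gaussian emissions of smoothed age factors;
  strongly non-Gaussian within-stage structure would distort stage
  boundaries.
* Leave-one-fish-out metrics are honest for the simulated cohorts; on
  real data, shared environment (tank position, cohort effects) could
  still couple training and held-out animals.
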