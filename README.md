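# lifespan-architect

Analysis pipeline for **lifelong behavioral aging** in individually housed,
continuously tracked fish (African turquoise killifish-style recordings:
6 body keypoints at 20 frames per second, 12 h light / 12 h dark, from
maturity until natural death). It turns raw keypoint tracks into
interpretable descriptions of how behavior reorganizes across a lifetime,
and ships a fully ground-truthed synthetic-data generator so every stage
can be validated without any recording hardware.

The pipeline, bottom to top:

1. **Pose features** (`pose_features`) — per-frame 57-dimensional feature
   vectors from the 6 keypoints: coordinates, low-pass-filtered velocities,
   snout acceleration, trailing-window snout *dispersion* (the inactivity
   statistic; sleep = dispersion below threshold for ≥ 60 s), whole-body
   bounding area, body length/segment proportions, visibility counts, wall
   distance, heading, body-bend angles α₁..₃, signed curvature angles
   θ₁..₃, reversal statistics, and a sleep flag, each expanded by 10-frame
   rolling mean (and std for the kinematic/shape subset). Features are
   z-scored and reduced to 15 principal components.
2. **Behavioral syllables** (`syllable_hmm`) — a K-state Gaussian hidden
   Markov model over the smoothed PCs; hidden states are stereotyped,
   reused behavioral motifs. Fitting uses memory-bounded **stochastic EM**:
   each update runs forward–backward on one contiguous batch of B frames
   and blends the batch's expected sufficient statistics into a running
   estimate with a Robbins–Monro step size ρ_t, so peak memory is O(BK²)
   rather than O(TK). K is selected by held-out log likelihood (plateau
   rule); syllables are clustered by symmetrized KL divergence of their
   Gaussian emissions.
3. **Behaviorome tensor** (`behaviorome_tca`) — syllable usage is binned at
   10-minute resolution into a syllable × time-of-day × animal-day count
   tensor (each 10-min bin holds 12,000 frames at 20 fps), min-max
   normalized per syllable, and factored by non-negative canonical
   polyadic decomposition X ≈ Σ_r aᵣ ∘ bᵣ ∘ cᵣ into syllable factors,
   time-of-day factors, and per-animal-day amplitudes — the **age
   factors**. Rank is chosen by cross-validation against held-out time
   bins using a normalized reconstruction error (a fraction-of-unexplained-
   variance analogue).
4. **Clocks and forecasts** (`aging_models`) — a leave-one-fish-out random
   forest **behavioral clock** estimating age from one day's age factors
   (Pearson R, per-age median absolute error, impurity importances, and a
   per-animal aging-rate slope); age-fixed random-forest classifiers
   forecasting whether an animal will live ≥ 200 days from its mean
   behavior over the 5 days before the prediction age (extreme agers
   > 300 d excluded); Kaplan–Meier curves and a log-rank test on the
   predicted groups; per-age Mann–Whitney U differential usage with
   Bonferroni correction.
5. **Life stages** (`life_stages`) — each day summarized as a 200-element
   light/dark syllable-usage vector; symmetrized Kullback–Leibler
   divergence between all day pairs reveals block structure; penalized
   RBF-kernel change-point detection (penalty ∝ ln of recorded days)
   locates discrete transitions; and a forward-ordered Gaussian HMM over
   smoothed, z-scored age factors assigns each day to one of six (by
   default) discrete life stages, summarized by empirical transitions,
   stage durations, usage profiles, and emission divergences.
6. **Synthetic data** (`synthetic_data`) — keypoint-level simulation of
   behavioral modes (rest, drift, cruise, burst, reversal, glass surfing)
   with i.i.d. keypoint jitter, exact ancestral sampling from Gaussian
   HMMs, and lifelong cohorts with bimodal (long/short) lifespans,
   forward-only life stages with shifted-geometric dwell times, and
   circadian usage templates with seven feeding-time activity peaks — all
   with truth labels returned.

## Worked example

Simulate a 12-animal lifelong cohort (20 syllables, 48 bins/day, 3 life
stages), factor it, and run the clocks and stage detection:

```python
import numpy as np
from lifespan_architect.synthetic_data import SimConfig, CohortSpec, simulate_syllable_cohort
from lifespan_architect.behaviorome_tca import normalize_usage, fit_nonneg_cp, normalized_error
from lifespan_architect.aging_models import age_factor_table, fit_behavior_clock, forecast_lifespan
from lifespan_architect.life_stages import (
    daily_usage_from_tensor, detect_change_points, fit_stage_model, stage_summaries)

cfg = SimConfig(n_syllables=20, n_bins_per_day=48, seed=1)
spec = CohortSpec(n_stages=3, mean_dwell_days=60, min_dwell_days=20,
                  template_separation=8.0)
tensor, truth = simulate_syllable_cohort(12, spec, cfg)
tensor = normalize_usage(tensor)
model = fit_nonneg_cp(tensor, rank=4, seed=1, n_restarts=1, max_iter=200)
factors = age_factor_table(model, tensor)
clock = fit_behavior_clock(factors, seed=1)
lifespans = dict(zip(truth.animal_ids, truth.lifespans_days.astype(float)))
fc = forecast_lifespan(factors, lifespans, prediction_age=100.0, window=15.0, seed=1)
usage = daily_usage_from_tensor(tensor, cfg.light_bins)
sel = tensor.animal_ids == "fish001"
cp = detect_change_points(usage[sel], days=tensor.ages[sel])
stage = fit_stage_model(model.age_factors, tensor.animal_ids, tensor.ages,
                        K_stages=3, seed=1)
summ = stage_summaries(stage)
```

Key numbers from this run (seed 1):

```
tensor shape (syllables, bins, animal-days): (20, 48, 2002)
normalized reconstruction error: 0.0024
behavioral clock held-out Pearson R: 0.807
lifespan forecast at day 100: AUC 1.0  accuracy 1.0
fish001 change points (days): [ 78. 104.]   true: [ 78 104]
stage transition matrix:
 [[0.984 0.016 0.   ]
  [0.    0.988 0.012]
  [0.    0.    1.   ]]
median stage durations (days): {0: 53.0, 1: 54.0, 2: 72.5}
```

Reading this: the rank-4 decomposition explains > 99% of usage variance on
this synthetic cohort; the behavioral clock recovers age ordering from age
factors alone (R = 0.81 — stage-structured behavior carries age
information, but within a stage days look alike); the forecaster separates
long- from short-lived animals perfectly because the generator gives the
groups distinct day-time inactivity; both of fish001's true stage
transitions are found to the day; and the fitted life-stage model is
forward-progressing (no backward transition mass) with multi-week stage
dwells.

The same flow runs from a shell:

```bash
lifespan-architect run --seed 1 --out results/demo
lifespan-architect simulate-cohort --n-animals 12 --seed 1 --out cohort.h5
lifespan-architect tca --tensor cohort.h5 --rank 45 --out model.h5
lifespan-architect features --track results/demo/track_00.csv --out feats.h5
```

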