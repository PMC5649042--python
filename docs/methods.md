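# Methods

This note documents the models, conventions and design choices behind
`actiwell`, in the order the pipeline runs.

## Time base

All nightly logic uses a "minutes since 21:00" axis: the axis for study
day *d* begins at 21:00 on the previous calendar evening and spans 1440
minutes, so nights never wrap midnight. The night that starts on that
evening belongs to day *d* (sleep precedes the day's mood reports).
Timestamps in all files are unix seconds; the conversion is internal.

## Synthetic cohort generator

The generator emulates a smartphone field study: bursts of ~3 s of
tri-axial accelerometer samples every 5 minutes, and up to four 9-point
mood/energy surveys per day inside fixed clock windows between 08:00 and
22:00.

**Schedules.** Each participant has a mean sleep onset (default ~23:30 ±
40 min across people) and offset (~07:30 ± 40 min), jittered night to
night by `schedule_jitter_sd` (default 30 min) and snapped to the 5-min
observation grid. Slots inside the nightly block are *still* with a
per-night stillness probability (mean 0.88, day-to-day SD 0.06),
modelling restless nights; daytime slots are *active* with a per-day
probability (person mean uniform on 0.15–0.45, day-to-day SD 0.08);
everything else is *other*. Two structural guarantees make the block
identifiable from state calls alone: the slots bordering the block are
forced active (people move when going to bed and getting up), and an
active slot is anchored at least every `max_sedentary_min` (default 90)
of waking time — without the anchors, a sedentary day can produce a
not-active run longer than a short night, and the run-scan sleep
estimator would return the wrong window. Anchoring is skipped for
zero-activity profiles, which are degenerate by construction. Dropout
removes whole bursts independently with `missingness_prob` (default
0.05).

**Burst waveforms.** Still bursts are gravity (9.81 m/s², random
orientation) plus white noise (SD 0.05 m/s²). Active bursts use a stride
model: lateral sway at *half* the step rate plus a vertical bounce at the
step rate (f0 uniform on 1.5–2.5 Hz, amplitude 1.5–3.5 m/s², noise SD
0.3). The sway is deliberate: gravity subtraction removes the mean
vector, so the norm of any zero-mean single-axis oscillation is full-wave
rectified and its spectral peak doubles; the squared sway restores the
step rate as the dominant frequency, as in real gait magnitude spectra.
"Other" bursts are gravity plus broadband noise of intermediate amplitude
(0.2–0.8 m/s²). Sample times are jittered by ±20% of the nominal period
to exercise the interpolation path.

**Well-being.** A latent daily level is
`intercept + Σ_k (β_k + b_ik) x_ik + ε`, with x the *within-person
z-scored realized* daily measures (sleep hours, active fraction of the
waking period, still fraction of the nightly block) and [0, 1]-scaled
time covariates; b_i are per-person Gaussian random effects (default SD
0.15 per term) and ε daily noise (default SD 1.0). Each survey response
adds response noise (SD 0.3), is rounded half-up and clipped to 1–9.
Surveys are answered with probability 0.8 per window, matching roughly
3.2 responses/day. The default coefficients are the effect sizes the
population analysis reports (mood: intercept 5.056, day −0.059, weekday
0.040, sleep 0.072, activity 0.097, stillness 0.040; energy: 5.686,
−0.304, 0.196, −0.027, 0.182, 0.024), so recovery experiments are
closed-loop.

**What it does not emulate:** device heterogeneity, diurnal survey
compliance patterns, vehicle travel, correlated (bursty) dropout, and
autocorrelated mood. Passing tests therefore show the pipeline's
correctness and statistical calibration under its stated model, not
performance on field data.

## Burst features

Gravity is the per-axis mean of the burst; the deviation magnitude is the
Euclidean norm after subtracting it (orientation-invariant; per-axis
features are useless when the phone's pose is free). The magnitude series
is linearly interpolated onto a 32 Hz grid — above twice any plausible
locomotion harmonic, power-of-two segments — between its first and last
timestamps (no extrapolation). Welch's method uses Hann windows, 32-sample
(1 s) segments, 50% overlap, no detrending (≥5 averaged segments per
burst); series shorter than a segment fall back to a single segment. The
spectral features are computed on the mean-centered magnitude so that the
large positive DC level of a norm cannot leak through the Hann main lobe
into the 1 Hz bin. The 8 features: mean, SD, dominant non-DC frequency,
spectral entropy (natural log over normalized non-DC bins; zero spectrum
→ 0), and integrated power in (0, 1], (1, 5], (5, 16] Hz plus their total.
Bursts with fewer than 4 samples or spanning more than 6 s are rejected
and become missing observations. Degenerate all-zero-deviation bursts get
entropy 0 and dominant frequency 0 by convention.

## Activity inference

Two one-vs-rest logistic regressions on the 8 features: a still detector
and a physical-activity detector. The penalty applies to the mean
log-loss (so fits are invariant to duplicating the training set) and its
weight is chosen by held-subject-out grid search over 10^{−3..3};
standardization statistics come from training data only. When both
detectors fire, still wins: a set-down phone produces near-zero deviation
regardless of the activity model. The classification threshold is 0.5,
exposed in config. Zero-variance features are dropped with a warning.
Held-out evaluation is leave-subject-out, retraining everything per fold.

## Daily measures

- **Sleep duration**: longest contiguous run of not-physically-active
  observations in the night window; a run breaks on an active observation
  or a gap > 1.5 × the observation interval (7.5 min), so missing
  stretches do not silently extend sleep. Run duration is last-minus-first
  timestamp (a single observation has duration 0 — no unobserved time is
  invented).
- **Median windows**: per day, the longest still run (for the late-evening
  window) and the not-active run (for wake/rest times) are collected;
  medians over days use the lower order statistic, keeping windows on
  observed minute marks. The active window runs from the median wake time
  to the median rest time of the *following* evening, so its end can
  exceed 1440 on the night axis (up to 2880); the day's observations
  naturally extend into that span.
- **Fractions**: observations inside the closed window, flagged still
  (nighttime stillness) or active (daytime activity); an empty window
  yields a missing value for that day.
- **Inclusion**: a complete day has ≥1 survey response and ≥1 valid
  burst; participants need ≥14 complete days. Behavior measures are
  z-scored within person (SD 0 → column of zeros with a warning); day of
  study and weekday (Monday=0..Sunday=6) are scaled by n_days−1 and 6.

## Population models

Maximum likelihood (never REML) so log-likelihoods are comparable across
fixed-effects structures. The maximal model gives every predictor a
correlated random slope plus a random intercept (unstructured
covariance). Convergence requires optimizer success and a maximum
per-observation score component < 1e-3; the raw score is O(n) and an
absolute threshold would be meaningless. The optimizer chain is
lbfgs → cg → powell: lbfgs occasionally reports success at a singular
boundary with infinite likelihood. On non-convergence the random term
with the smallest estimated variance is removed (never the intercept;
ties broken by a fixed preference order) and the model refit — at most
one reduction per removable term. Degenerate data (exact linear fit or
constant outcome) short-circuits to least squares with the residual
variance floored at 1e-12 so the likelihood stays finite. The fit ladder
compares random-intercept-only → fixed effects + random intercept →
reduced-maximal, with chi-square df equal to parameter-count differences
(5 for the fixed effects; q(q+1)/2 − 1 for a q-term random structure).
Fixed-effect t tests use residual df and are descriptive.

## Personal prediction

Bad days are days strictly below the person's median outcome (ties are
"fine"); classification needs ≥5 days of each class, regression ≥10 days
(the inner cross-validation needs a real training set). Outer evaluation
is leave-one-out; within each outer fold the penalty is selected by an
inner leave-one-out over 13 logarithmic grid points in 10^{−3..3}
(elastic-net mixing fixed at 0.5). The classification model is the better
of L1/L2 logistic by inner error. The held-out day enters neither the
outer fit nor the inner selection; fold hashes make this auditable.

The inner search solves all folds and grid points simultaneously with a
vectorized FISTA solver of exactly the scikit-learn objectives
(per-alpha step sizes; 300 iterations); the outer-fold model that
produces predictions is a scikit-learn fit. This keeps the nested
protocol exact while fast enough for cohort-scale use.

Baselines: for classification, one constant prediction per person —
their most frequent class, ties "fine" (a leave-one-out training
majority flips against every held-out day under a balanced split and
scores 100%, which is not a "most common state" prediction); for
regression, the leave-one-out training median, scored by RMSE. User lift
is baseline error minus model error (percentage points for
classification, RMSE difference for regression). Cohort significance
uses a one-sample sign-flip permutation test on per-person lifts,
p = (1 + #{permuted mean ≥ observed}) / (1 + n_perm), default
n_perm = 10,000 with a permutation seed separate from the data seed.

## Pipeline

One master seed derives fixed per-stage child streams (profiles,
timelines, training bursts, surveys, cohort bursts), so identical config
and seed give byte-identical outputs; the manifest records config,
seeds, counts and SHA-256 checksums. Stages are file-to-file and never
mutate other stages' outputs. Schema validation checks column presence,
ranges (Likert 1–9, probabilities, fractions, weekday 0–6) and
within-burst timestamp monotonicity.

## Problem sizes

The recovery experiment in `scripts/acceptance.py` uses 20 replicates of
50 participants × 56 days (the scale of an 8-week cohort), fitted for
both outcomes; unit tests use cohorts of 3–12 participants and 16–40
days, which keeps the full suite at a few minutes while still exercising
every stage at realistic per-person sizes.

## Known limitations

- With nonzero dropout the gap-tolerance rule shortens extracted sleep
  runs (a single missing burst breaks contiguity); sleep estimates under
  dropout are conservative. The recovery experiment therefore runs
  without dropout, which is also the regime where ground-truth recovery
  is exactly verifiable.
- Nighttime stillness is measured inside a median window estimated from
  still runs, so its correlation with the generative per-night stillness
  is ~0.8; its fitted coefficient is attenuated accordingly. This mirrors
  the measure's noisiness on real data.
- The synthetic burst classes are more separable than field data;
  held-out classifier accuracy near 1.0 should be read as "the pipeline
  is correct", not as an expected field accuracy.
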