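# Methods

## The screening model

The package treats cognitive screening as a regression problem: estimate an
MMSE score (0–30) from twelve behavioural features of one dual-task
session, then threshold the estimate at 24 to flag possible impairment.
The regression-then-threshold design is deliberate — the score carries more
supervision than the binary label, and thresholding a well-calibrated
estimate discriminates better than training a classifier on the label
directly.  The evaluation unit is the trial; since a subject's MMSE is
constant across trials, leave-one-subject-out (LOSO) cross-validation is
essential: any split that lets a subject's other trials into training would
leak identity and grossly overstate accuracy.  A per-subject
majority-vote aggregation is available (`EstimationResult.to_subject_level`)
for settings where the subject is the unit of report.

## Features

Each session has three phases: arithmetic only (30 s), stepping in place
(20 s), both at once (30 s).  Per task context (single, dual):

| feature | definition | units |
| --- | --- | --- |
| step_interval_mean / _sd | moments of Δt between successive alternating-foot floor contacts | s |
| knee_amplitude_mean / _sd | moments of per-raise-cycle amplitude of the knee angle | rad |
| answer_rate | correct answers / answered questions | — |
| answer_time_mean | mean time from candidate display to button press | s |

Stepping speed is represented as the inter-step interval itself, not a
rate; the monotone relations downstream simply reverse sign.  The knee
angle is the interior angle at the knee between the knee→hip-centre and
knee→ankle segments, which normalises knee-lift height across statures; it
is computed as `atan2(|u×v|, u·v)` for stability near 0 and π.  Consecutive
same-foot contacts (sensor glitches) contribute no interval and are
logged.  Standard deviations are population (1/n) by default with a sample
(1/(n−1)) switch; left- and right-leg cycles are pooled into one amplitude
sample.  Trials missing any feature are excluded from modelling
(complete case).

### Gait-cycle segmentation

Flexion valleys are local minima of the angle trace after a centred
moving-average smoothing (window 0.3 s), subject to a minimum prominence
(0.05 rad) and minimum separation (0.4 s); the defaults are sized to adult
stepping cadence (raise cycles of roughly 1–1.5 s and amplitudes of
0.2–0.7 rad).  Each valley is paired with the larger raw-angle maximum on
its two flanks (the extended, near-floor angle).  Extremum *values* are
read from the raw series at a refined index near the smoothed extremum, so
smoothing cannot attenuate amplitudes.  One numerical limit remains: the
extension peak between two abutting raises is a cusp, and at a 30 Hz frame
rate the nearest sample can sit half a frame away, bounding the per-cycle
amplitude error by about `A·sin(π·Δt/2/d)` ≈ 0.03 rad (A amplitude, d cycle
length); this sampling floor applies equally to real recordings.  All time
arithmetic uses timestamps, so the pipeline does not require uniform
sampling.

## The synthetic cohort generator

The generator defines the study conditions for every test in the package.
Subject MMSE is a rounded normal clipped to [0, 30], calibrated to the
reference cohort (mean 24.6, SD 5.24 over 90 subjects; 32 males of mean
age 81.5 y, 68 females of 82.6 y).  Clipping at 30 pulls the realised
sample mean about 0.4 points below the nominal mean — an accepted property
of the model, well inside the sampling band at n = 90.

Latent behavioural parameters are linear in the deficit `d = 30 − MMSE`
plus subject-level Gaussian noise:

* knee-raise amplitude: 0.55 − 0.012·d rad (SD 0.05),
* step interval: 0.60 + 0.004·d s (SD 0.04),
* single-task step jitter: 0.02·(1 + 0.03·d) s with log-normal
  subject scatter (σ = 0.15),
* answer accuracy: 0.97 − 0.010·d (SD 0.03), response time
  2.0 + 0.05·d s (SD 0.30).

Dual-task costs are multiplicative and linear in the deficit with zero
cost at MMSE 30 — per deficit point: ×(1+0.10) on step jitter, ×(1+0.005)
on the interval, ×(1−0.006) on amplitude, ×(1−0.004) on accuracy,
×(1+0.02) on response time.  This encodes cognitive-motor interference:
the same subject is noisier, slower and flatter-kneed under load, more so
the lower the score.  Subjects at or above the awareness gate (MMSE ≥ 24)
additionally gain 0.004 rad of knee-raise amplitude per completed trial,
plateauing at trial 40 — modelling the practice effect of seeing one's
printed results.  Baselines and effect sizes are plausible desk-scale
values chosen once; the reference deployment reports no generative model,
so all of them live in `CohortConfig`.

Sessions are synthesised from the bottom up: alternating floor contacts
with the configured interval and jitter; a per-leg knee-angle trace that
dips by a per-cycle amplitude (half-sine between consecutive same-foot
contacts); and raw 3-D joint positions (fixed hip centre, ankle swung
about the knee) constructed so the knee-angle formula is exercised on
points rather than on pre-made angle series, with optional Gaussian
position noise (default 2 mm).  Arithmetic responses follow the subject's
accuracy and speed through the same question generator used for scheduling
(operands 1–49 for addition, minuend ≤ 99 for subtraction; distractors by
dropped carry/borrow, ±1 on the units digit, or operator swap — a rule that
reproduces the correct answer is resampled).  True angle traces and
scheduled per-cycle amplitudes are exposed in each phase's `truth` payload
so extraction can be validated against the generator.

What the generator does *not* emulate: skeleton-tracking dropouts and
occlusions, within-session fatigue, day-to-day drift of ability,
non-stationary cadence, unanswered questions, or correlations between
demographics and behaviour beyond the MMSE link.  Passing tests therefore
demonstrate the correctness and sensitivity of the pipeline under the
modelled effect structure, not clinical performance on real recordings.

## Regressors

* **linear_svr** — ε-insensitive linear SVR (C = 1, ε = 0.1), features
  standardised on training-fold statistics.  Targets are standardised too
  (via a target transformer) because liblinear regularises the intercept;
  raw 0–30 targets would otherwise be under-fitted.
* **random_forest** — 500 trees, p/3 features per split, no scaling.
* **bayes_nn** — one-hidden-layer tanh network, linear output, trained by
  Levenberg–Marquardt on the regularised objective β·E_D + α·E_W with
  MacKay evidence re-estimation of α and β each accepted step.  Raw
  evidence updates oscillate on small networks and can strangle a fit
  early (α overshoots while the weights are still small), so the updates
  are geometrically damped: α ← √(α·α*).  The width is selected from
  {1, 2, 3} by an inner 10-fold CV RMSE grid inside each training fold;
  inner fits use a shorter iteration cap (8) than the final fit (15),
  since ranking three widths converges faster than polishing the winner —
  raising both caps changes the headline sum by < 0.01.  Predictions are
  clipped to [0, 30].

Per-fold randomness is keyed on `(master seed, subject id)` and the
dataset is canonically sorted inside `loso_cv`, so results are invariant
to row order.

## Cohort analyses

* **Importance** is the R² of a univariate linear fit of the
  cross-validated predictions on each feature — "how much of the model's
  output this feature explains".  The regression target of the published
  coefficient-of-determination importance is underdetermined; this
  reading was chosen because it is computable for every regressor family
  and reduces to the intuitive 1.0 for a feature identical to the
  predictions.  A permutation-importance alternative on a full-data fit is
  available behind `method="permutation"`.
* **Ablation** removes one base feature type from both contexts
  (12 → 10 columns) and re-runs LOSO.
* **Feature sets** compares single-physical (4), single-cognitive (2),
  single-all (6), dual (6) and combined (12) columns.
* **Trial groups** retains subjects whose trial count reaches 100
  (inclusive by default — only the inclusive reading lets a subject with
  exactly 100 trials populate all five 20-trial groups; a strict `>` flag
  exists) and reports metrics, importance and physical-feature means per
  group.
* **Experience contrasts** compare subjects' first-trial values against
  their per-subject means over trials ≥ 41 (one value per subject, so the
  t-test's independence assumption holds), per MMSE stratum and measure,
  with Welch's two-tailed t-test by default (a pooled-variance switch
  exists) and Bonferroni correction over all contrasts of one invocation.

## Problem sizes and numerical choices

The default study cohort is 60 subjects × 20 trials — large enough that
the NN pipeline's recall + specificity comfortably exceeds 1.5 under the
default effect sizes, small enough for interactive use.  Constructed
cohorts for structure-recovery checks use 40 × 8 (ablation, feature sets)
and 16 × 45 (experience contrasts).  Degenerate inputs fail loudly:
constant targets, single-subject datasets, empty response lists, zero-
length limb segments and unknown schema versions all raise typed errors;
a subject standing still yields an empty cycle list (a missing-feature
signal), not a crash.  Ties in the width grid resolve to the smaller
network.

## Known limitations

The simulator's half-sine leg-lift and fixed hip are kinematically
idealised; joint noise is isotropic Gaussian, unlike structured Kinect
artefacts.  Importance scores are univariate and ignore feature
interactions.  The Bayesian NN uses a single random initialisation per
fit; the damped evidence updates make collapses rare but not impossible.
Recall/specificity are reported per trial, which weights frequent
participants more heavily — use the subject-level aggregation when that
matters.
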