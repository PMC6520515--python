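# Methods

## The task and the analysis model

The package analyzes a three-choice object localization task: a head-fixed
mouse whisks a single whisker against a vertical pole presented at one of
three anterior–posterior locations and reports the location by licking left,
licking right, or withholding licks. Choices are labeled by the location for
which they are correct, so pole locations and choices share the label set
{posterior, middle, anterior} and the location→correct-choice mapping is a
bijection (identity under this labeling).

The central statistical object is a maximum-a-posteriori (naive Bayes)
classifier over per-trial predictors x₁…x_R,

P(y = k | x₁…x_R) ∝ π(k) · ∏ⱼ P(xⱼ | y = k),

whose key assumption is conditional independence of the predictors given the
class. Priors are training-set class frequencies. Categorical conditionals
are within-class level frequencies (multinomial); continuous conditionals
are within-class Gaussians. The Gaussian choice is an approximation: within
a pole-location class the Δκ95 predictor is really a mixture (no-touch
zeros, protraction-positive and retraction-negative components), so the
fitted conditional is a moment-matched Gaussian over that mixture. This is
deliberate — it is the standard form of this classifier family — and the
class-separation it can express is correspondingly conservative.

Evaluation is tenfold cross-validation with trials randomly allocated to
folds (sizes differing by at most one) and predictions concatenated across
folds. Chance levels for classifier metrics are obtained by permuting the
labels relative to the predictors and repeating the entire cross-validated
fit 50 times; behavioral chance levels (task performance, perseveration) use
10,000 permutations of the relevant sequence. All confidence intervals are
percentile intervals (2.5th–97.5th) of the permutation distribution.

## Predictor definitions

- **PAT**: 1 if the trial contains at least one touch episode, else 0.
- **Touch episodes**: maximal runs of frames with whisker–pole distance
  below a threshold (a free parameter, default 0.5 mm, mirroring the
  per-session user-set thresholds of practical touch curation). Frames that
  failed tracking QC are "dropped": isolated drops are repaired by linear
  interpolation from the flanking frames; runs of two or more remain
  unresolved and split any episode they interrupt (logged as a warning).
- **Touch type**: direction of the first episode from the whisking phase at
  its start frame (first resolved frame if the start was dropped). Phase is
  the angle of the analytic signal (Hilbert transform) of the mean-removed,
  band-passed whisker angle. Band: 4–30 Hz, second-order Butterworth applied
  forward-backward (zero phase), configurable; the band brackets the
  5–25 Hz whisking rhythm. Convention: phase in [−π, 0) = protraction
  (angle rising), [0, π) = retraction; values of exactly 0 or ±π (measure
  zero, but reachable in floating point) go to retraction.
- **Δκ95**: baseline = median κ over the 6 frames immediately preceding the
  first episode's start frame (exclusive); Δκ(f) = κ(f) − baseline over the
  episode's resolved frames; the statistic is whichever of the 5th/95th
  percentile of {Δκ(f)} has the larger absolute value, 0 by definition when
  no touch occurred. Percentiles interpolate linearly between order
  statistics (the numpy default; the convention is stated because the
  definition does not fix one, and the test oracle uses the same rule). An
  exact |5th| = |95th| tie returns the 95th, matching the
  protraction-positive sign convention. If all six baseline frames are
  dropped the trial is flagged unusable and excluded downstream (the
  analogue of the retrack-or-discard rule for corrupted first touches).
- **Whisking amplitude**: envelope (magnitude of the analytic signal) of the
  band-passed angle, in degrees.
- **Previous choice type**: previous trial's choice × correctness, six
  levels; undefined on each session's first trial, which is excluded from
  every previous-choice computation.

## Classifier numerics

- Log-domain posterior accumulation; categorical cells with zero training
  frequency (and categories unseen in training) contribute a floor
  probability of 1e−9 — small enough never to move a MAP decision that has
  any support, large enough to avoid −∞.
- Gaussian SDs are floored at 1e−6 in predictor units (degenerate
  zero-variance classes are logged).
- Posterior ties are broken toward the earlier class in the fixed order
  (posterior, middle, anterior), applied with a 1e−9 relative tolerance so
  the decision is independent of whether a tied posterior was accumulated in
  the log or linear domain.
- Cross-validation partitions that leave a class absent from some training
  split are resampled (bounded retries) before failing.
- In the dissociation analysis both classifiers (sensory: touch type + Δκ95;
  history: previous choice type) share one fold assignment over all
  evaluable trials, and accuracies are then computed per correctness subset;
  per-subset chance intervals permute the choice labels and repeat the
  shared-fold cross-validation. Perseveration nulls permute the full choice
  sequence and re-evaluate on the original subset positions, preserving the
  subset structure.

## The synthetic generator

The generator reproduces the statistical structure the analysis assumes,
not whisker biomechanics:

- **Pole sequence**: i.i.d. draws from the location probabilities, redrawing
  any draw that would extend a run of identical locations past `max_run`
  (default 3) — a constrained randomization in the style of behavioral
  "AB" sequencing. Degenerate demands (one location with probability 1 and
  more trials than the run cap) raise an error.
- **Whisking**: θ(t) = setpoint + A(t)·cos(2πft + φ₀) + Gaussian noise, with
  A ramping linearly from `amp_pre` (1°) to `amp_post` (15°) over 100 ms at
  pole onset — mice whisk little until the pole arrives. Defaults: 15 Hz,
  setpoint 100°, angle noise SD 0.5°, 1 kHz frames.
- **Touches**: a trial is touched with a location-dependent probability
  (0.87 / 0.93 / 0.46 for posterior / middle / anterior — the touch
  statistics of the task this emulates); the first touch's direction is
  drawn per location (posterior mostly retraction, middle/anterior mostly
  protraction), later touches repeat the previous direction with
  probability 0.94. The touch count distribution (0.35/0.25/0.24/0.10/0.06
  for 1–5 touches) puts 84% of touched trials at ≤3 touches. Touches occupy
  the middle of distinct monotone half-cycles of the (smoothed) angle trace,
  so the phase at touch onset matches the intended direction by
  construction. During a touch the pole distance drops to 0 (3 mm
  otherwise) and the curvature rises over a half-cosine ramp to a 3-frame
  plateau at a peak drawn from the Gaussian of (location, direction), then
  falls symmetrically. The plateau ensures the 95th-percentile statistic
  attains the drawn peak exactly on noiseless data, making generator truth
  an exact oracle for Δκ95.
- **Peak statistics**: the peak draw is sign-enforced,
  sign(direction)·|N(μ, σ)|, so the protraction-positive/retraction-negative
  convention holds exactly even in noiseless mode. Defaults (free
  parameters; the emulated task reports these distributions only
  graphically): protraction means +0.008/+0.016/+0.028 mm⁻¹ for
  posterior/middle/anterior, retraction mirrored at −0.028/−0.016/−0.008,
  SD 0.004 mm⁻¹. Adjacent means are ≥2 SD apart so bending magnitude
  carries location information beyond direction alone, and |mean| ≥ 2σ
  keeps the folded-Gaussian bias of the sign-enforced draw (≈3% of σ at
  worst) negligible against estimation error at the sample sizes used.
  The exact generative moments of the folded draw are available in closed
  form and serve as the oracle in parameter-recovery tests.
- **Dropped frames**: each frame drops with probability 0.001, kept
  isolated; dropped frames carry NaN values. Noiseless mode switches off
  angle noise, curvature noise and frame drops together.
- **Choices**: with probability λ (`p_perseverate`, default 0.25) the mouse
  repeats its previous choice; otherwise it answers from the pole location,
  lapsing to a uniformly random choice with probability ε (`sensory_noise`,
  default 0.15). The first trial is always sensory-guided. The defaults put
  session performance near 0.74 with a material perseverative component;
  λ = 0.5, ε = 0 produces the clean double dissociation used in testing.

What the generator does **not** emulate — and hence what passing tests do
not establish about real recordings: continuous whisker kinematics during
contact (the angle trace is unperturbed by touch), set-point drift and
inter-whisk variability, amplitude-dependent touch probability, correlated
or burst-like frame drops, session-to-session nonstationarity, and any
coupling of the mouse's choice to the actual trial-by-trial sensory
features (the synthetic mouse reads the true location, not its whisker).
Conclusions about real data require the real frame series; the synthetic
suite validates the computations, not the biology.

## Problem sizes and tolerances

The default analysis scale is 5 synthetic mice × 760 trials of 1500 ms
(pole onset 500 ms), matching the per-animal trial counts typical of this
task family; unit tests use sessions of 100–500 trials of 800 ms to keep
the suite fast while leaving ≥3 cycles of the 4 Hz band edge for the
Hilbert machinery (the filter needs at least 750 frames). The acceptance
suite checks: exact agreement with brute-force posterior enumeration on
small categorical problems; Δκ95 against an independent sorted-percentile
oracle to 1e−12; episode boundaries to ±1 frame and direction recovery
≥99% (noiseless) / ≥95% (default noise); Gaussian parameter recovery
within 3 standard errors at ~1,000 trials per class; strict performance
ordering PAT < touch type < touch type + Δκ95 at the default scale; the
double dissociation with λ = 0.5, ε = 0 against shuffle-null bounds;
95% ± 3% coverage of the 10,000-shuffle performance CI over 500 null
sessions; and byte-identical end-to-end reports under a fixed seed.

## Known limitations

- The Gaussian conditional on Δκ95 is a mixture approximation (above); a
  nonparametric conditional would be sharper but is not implemented.
- Touch placement requires an oscillatory angle trace; with very low
  whisking amplitude the half-cycle segmentation can find no host segment
  and a nominally "touched" trial is emitted without touches.
- The choice-consistency chance interval shuffles the location labels and
  reruns cross-validation; alternatives (e.g. shuffling choices against
  fixed predictions) answer slightly different questions and are not
  provided.
- `perseveration_by_previous_outcome` reports point estimates with stratum
  sizes; chance bands for the conditional probabilities can be obtained by
  applying `perseveration` with the corresponding masks.
- The pipeline's CSV round-trip truncates frame values to 6 decimals;
  in-memory analysis (`analyze_cohort`) avoids this.
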