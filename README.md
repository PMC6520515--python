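# whiskmap

Analysis pipeline for three-choice, whisker-guided object localization in
head-fixed mice. A mouse palpates a vertical pole with a single whisker and
reports the pole's anterior–posterior position (posterior / middle /
anterior) by licking left, licking right, or withholding licks. `whiskmap`
quantifies which mechanosensory cues could support those decisions — and
when the mouse instead just repeats itself — from tracked whisker time
series, with every stage testable against a synthetic session generator.

It is intended for behavioral neurophysiologists working with high-speed
whisker tracking (1 kHz angle θ, curvature κ and whisker–pole distance per
frame) plus a trial table (pole location, choice, correctness).

## What it computes

**Per-trial predictors** (`whiskmap.features`)

- *PAT* — presence/absence of whisker–pole touch (binary);
- *touch type* — direction of the first touch, protraction / retraction /
  none, from the Hilbert phase of the band-passed whisker angle;
- *Δκ95* — a noise-robust index of bending-moment magnitude: over the first
  touch episode, Δκ(f) = κ(f) − median κ of the 6 ms before touch onset, and
  Δκ95 is whichever of the 5th or 95th percentile of {Δκ(f)} is larger in
  magnitude (0 when no touch occurred);
- *previous choice type* — the previous trial's choice × its correctness
  (six levels).

**MAP classification** (`whiskmap.classifier`). Pole location (or mouse
choice) y is predicted from predictors x₁…x_R assumed conditionally
independent given y:

    P(y = k | x₁…x_R) ∝ π(k) · ∏ⱼ P(xⱼ | y = k)

with π(k) the training-set class frequencies, multinomial conditionals for
categorical predictors and Gaussian conditionals for continuous ones; the
prediction is the posterior argmax. Evaluation uses tenfold cross-validation
with predictions concatenated across folds; chance levels come from
shuffling the labels and repeating the whole cross-validated fit (50
iterations). Two metrics: *performance* (fraction of trials with pole
location predicted correctly) and *choice consistency* (fraction of trials
where the classifier's implied choice matches the mouse's).

**Behavioral statistics** (`whiskmap.behavior`): task performance against a
10,000-shuffle chance interval, learning and asymptotic-performance criteria
across sessions, perseveration P(choiceₜ = choiceₜ₋₁) on all / correct /
error trials with its own shuffle chance, the sensory-vs-history double
dissociation (which classifier predicts the mouse's choice on correct vs
error trials), touch-sequence descriptives and a χ² choice-bias test.

**Synthetic sessions** (`whiskmap.simulate`): run-capped pseudorandom pole
sequences, set-point-centred whisking with an amplitude ramp at pole onset,
location-dependent touch probability and direction, curvature transients
with (location, direction)-dependent peak statistics, and a choice policy
mixing sensory-guided responses with perseveration. Ground truth (episode
intervals, directions, peaks) is returned for every trial.

## Worked example

```
whiskmap all --config example.toml --outdir demo
```

with `example.toml`:

```toml
[run]
seed = 7
n_mice = 2

[sim]
n_trials = 200

[classifier]
shuffle_iters = 20

[analysis]
n_shuffles = 2000
```

prints nothing and writes `demo/report.txt`:

```
whiskmap run report
seed=7  config_hash=09deeb5ca7b9c551
mice=2  trials/mouse=200

classifier performance / choice consistency (mean across mice):
  pat                    0.503 ± 0.067 / 0.425
  touch_type             0.748 ± 0.025 / 0.585
  dkappa95_touch_type    0.752 ± 0.018 / 0.590
  previous_choice        0.294 ± 0.089 / 0.249

mouse performance: 0.772
perseveration all/correct/error: 0.440 / 0.348 / 0.750
choice prediction on error trials, sensory vs history: 0.066 vs 0.660
choice prediction on correct trials, sensory vs history: 0.749 vs 0.339
```

Reading it: touch presence alone predicts pole location at 0.50 — far below
the simulated mouse (0.77) — because two of the three locations are touched
on nearly every trial. Adding touch *direction* raises performance to 0.75,
and the Δκ95 bending magnitude adds a further increment by separating
locations that share a touch direction. The behavioral block shows the
signature of a mouse that mixes sensation with habit: errors are mostly
perseverative (perseveration 0.75 on error trials vs 0.35 on correct ones),
so on error trials the previous-choice classifier predicts the mouse's
choice far better than the sensory classifier (0.66 vs 0.07), while the
ordering reverses on correct trials (0.34 vs 0.75). `demo/report.json`
carries the same content machine-readably, including per-mouse values and
shuffle chance intervals; `trials.csv`, `frames_*.csv` and `predictors.csv`
hold the intermediate artifacts. Reruns with the same config and seed are
byte-identical.

The same analyses are available as a library, e.g.

```python
import numpy as np
from whiskmap import (SimConfig, BehaviorPolicy, generate_session,
                      extract_session_features, build_predictor_table,
                      dissociation_analysis)

sess = generate_session(SimConfig(n_trials=760), BehaviorPolicy(),
                        np.random.default_rng(1))
pred = build_predictor_table(sess.trials,
                             extract_session_features(sess.frames))
print(dissociation_analysis(pred, np.random.default_rng(2)).history)
```

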