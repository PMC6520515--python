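"""Session-level behavioral statistics.

Covers the descriptive layer of the analysis: task performance against a
location-shuffle chance distribution, learning and asymptotic-performance
criteria across sessions, perseveration (repeating the previous choice) with
its own shuffle chance, the correct/error double dissociation between
sensory and choice-history classifiers, touch-sequence descriptive
statistics, and a choice-frequency bias test.

Chance levels throughout are percentile intervals (2.5th–97.5th) of a
10,000-permutation null, mirroring how behavioral chance is conventionally
calibrated for this task family.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classifier import (
    NullDistribution,
    classifier_performance,
    predict_mouse_choice,
    _make_folds,
)
from .simulate import LOCATIONS

__all__ = [
    "SessionSummary",
    "PerseverationResult",
    "DissociationResult",
    "task_performance",
    "learning_detector",
    "asymptotic_performance",
    "perseveration",
    "perseveration_by_previous_outcome",
    "dissociation_analysis",
    "touch_sequence_stats",
    "choice_bias_test",
]

#: Predictors of the sensory (bending) classifier in the dissociation.
SENSORY_KINDS = {"touch_type": "categorical", "dkappa95": "continuous"}
#: Predictor of the choice-history classifier.
HISTORY_KINDS = {"prev_choice_type": "categorical"}


@dataclass
class SessionSummary:
    """Performance of one session against its shuffle chance."""

    performance: float
    per_location: dict[str, float]
    chance_mean: float
    chance_lo: float
    chance_hi: float
    above_chance: bool
    n_trials: int


@dataclass
class PerseverationResult:
    probability: float
    chance_mean: float
    chance_lo: float
    chance_hi: float
    n: int

    @property
    def above_chance(self) -> bool:
        return self.probability > self.chance_hi


@dataclass
class DissociationResult:
    """Accuracy of sensory vs choice-history classifiers, split by the
    correctness of the mouse's choice."""

    sensory: dict[str, float]
    history: dict[str, float]
    sensory_chance: dict[str, tuple[float, float]]
    history_chance: dict[str, tuple[float, float]]
    n_correct: int
    n_error: int


def task_performance(
    trials: pd.DataFrame,
    n_shuffles: int = 10_000,
    rng: np.random.Generator | None = None,
    mapping: Mapping[str, str] | None = None,
) -> SessionSummary:
    """Proportion of correct trials, with chance from location shuffling.

    The null shuffles the pole-location sequence against the fixed choice
    sequence and recomputes the proportion correct; ``above_chance`` flags
    performance beyond the 97.5th percentile of that null.
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    if rng is None:
        rng = np.random.default_rng()
    if mapping is None:
        mapping = {loc: loc for loc in LOCATIONS}
    loc = trials["pole_location"].to_numpy(dtype=object)
    correct_choice = np.array([mapping[l] for l in loc], dtype=object)
    choice = trials["choice"].to_numpy(dtype=object)
    perf = float(np.mean(correct_choice == choice))
    per_location = {
        l: (float(np.mean(choice[loc == l] == mapping[l]))
            if np.any(loc == l) else np.nan)
        for l in LOCATIONS
    }
    # integer codes shuffle faster than object arrays
    uniq = list(pd.unique(np.concatenate([correct_choice, choice])))
    code = {v: i for i, v in enumerate(uniq)}
    a = np.array([code[v] for v in correct_choice])
    b = np.array([code[v] for v in choice])
    perm = np.argsort(rng.random((n_shuffles, len(a))), axis=1)
    null = (a[perm] == b[None, :]).mean(axis=1)
    lo, hi = np.percentile(null, [2.5, 97.5])
    return SessionSummary(
        performance=perf,
        per_location=per_location,
        chance_mean=float(null.mean()),
        chance_lo=float(lo),
        chance_hi=float(hi),
        above_chance=bool(perf > hi),
        n_trials=len(trials),
    )


def learning_detector(summaries: Sequence[SessionSummary]) -> int | None:
    """First 1-based session index opening a run of three consecutive
    above-chance sessions, or None if the mouse never reaches criterion."""
    flags = [s.above_chance for s in summaries]
    for i in range(len(flags) - 2):
        if flags[i] and flags[i + 1] and flags[i + 2]:
            return i + 1
    return None


def asymptotic_performance(
    summaries: Sequence[SessionSummary], window: int = 8
) -> float:
    """Mean performance over the latest run of ``window`` consecutive
    above-chance sessions (as close as possible to the end of training)."""
    flags = [s.above_chance for s in summaries]
    for i in range(len(flags) - window, -1, -1):
        if all(flags[i:i + window]):
            return float(np.mean([s.performance
                                  for s in summaries[i:i + window]]))
    raise ValueError(f"no window of {window} consecutive above-chance sessions")


def perseveration(
    choices: Sequence,
    subset_mask: Sequence[bool] | None = None,
    n_shuffles: int = 10_000,
    rng: np.random.Generator | None = None,
) -> PerseverationResult:
    """P(choice_t = choice_{t−1}) over selected current trials t ≥ 2.

    ``subset_mask`` restricts which *current* trials enter the statistic
    (e.g. error trials only); the previous trial is always the immediately
    preceding one regardless of the mask.  The null permutes the full choice
    sequence and recomputes the statistic on the same subset positions.
    """
    choices = np.asarray(choices, dtype=object)
    T = len(choices)
    if T < 2:
        raise ValueError("need at least two trials")
    if rng is None:
        rng = np.random.default_rng()
    if subset_mask is None:
        mask = np.ones(T, dtype=bool)
    else:
        mask = np.asarray(subset_mask, dtype=bool)
        if mask.shape != (T,):
            raise ValueError("subset_mask length mismatch")
    sel = mask[1:]
    n = int(sel.sum())
    if n == 0:
        raise ValueError("empty subset: no current trials selected")
    stat = float(np.mean((choices[1:] == choices[:-1])[sel]))
    uniq = list(pd.unique(choices))
    code = {v: i for i, v in enumerate(uniq)}
    c = np.array([code[v] for v in choices])
    perm = np.argsort(rng.random((n_shuffles, T)), axis=1)
    mat = c[perm]
    rep = mat[:, 1:] == mat[:, :-1]
    null = rep[:, sel].mean(axis=1)
    lo, hi = np.percentile(null, [2.5, 97.5])
    return PerseverationResult(
        probability=stat, chance_mean=float(null.mean()),
        chance_lo=float(lo), chance_hi=float(hi), n=n)


def perseveration_by_previous_outcome(trials: pd.DataFrame) -> dict:
    """Perseveration on error trials, split by the previous trial's outcome.

    Among current *error* trials (t ≥ 2), returns P(choice_t = choice_{t−1})
    separately for trials whose previous trial was correct vs an error.
    Empty strata yield NaN with n = 0.
    """
    if len(trials) < 2:
        raise ValueError("need at least two trials")
    choice = trials["choice"].to_numpy(dtype=object)
    correct = trials["correct"].to_numpy(dtype=int)
    rep = choice[1:] == choice[:-1]
    cur_err = correct[1:] == 0
    prev_ok = correct[:-1] == 1
    out = {}
    for label, stratum in (("prev_correct", prev_ok), ("prev_error", ~prev_ok)):
        m = cur_err & stratum
        out[label] = float(rep[m].mean()) if m.any() else float("nan")
        out[f"n_{label}"] = int(m.sum())
    return out


def dissociation_analysis(
    predictors: pd.DataFrame,
    rng: np.random.Generator | None = None,
    k_folds: int = 10,
    n_shuffles: int = 50,
) -> DissociationResult:
    """Sensory vs choice-history prediction of mouse choice, by correctness.

    Both classifiers predict the mouse's choice under one shared
    cross-validation fold assignment over all evaluable trials (usable
    feature extraction and a defined previous choice, i.e. not a session's
    first trial).  Accuracy is then reported separately on the correct-choice
    and error-choice subsets, alongside per-subset shuffle chance intervals
    obtained by permuting the choice labels and repeating the whole
    cross-validated fit.
    """
    if rng is None:
        rng = np.random.default_rng()
    df = predictors
    keep = df["usable"].to_numpy(dtype=bool) & df["prev_choice_type"].notna().to_numpy()
    df = df[keep].reset_index(drop=True)
    correct = df["correct"].to_numpy(dtype=int) == 1
    if not correct.any() or correct.all():
        raise ValueError("need both correct and error trials")
    choices = df["choice"].to_numpy(dtype=object)
    T = len(df)
    if min(correct.sum(), (~correct).sum()) < k_folds:
        import warnings
        warnings.warn("a correctness subset is smaller than the fold count; "
                      "per-subset accuracies may be unstable", stacklevel=2)
    folds = _make_folds(T, k_folds, rng)

    def _subset_acc(pred: np.ndarray, targets: np.ndarray) -> dict[str, float]:
        return {
            "correct": classifier_performance(pred[correct], targets[correct]),
            "error": classifier_performance(pred[~correct], targets[~correct]),
        }

    results, chances = {}, {}
    for name, kinds in (("sensory", SENSORY_KINDS), ("history", HISTORY_KINDS)):
        cv = predict_mouse_choice(df, choices, kinds, k_folds=k_folds,
                                  folds=folds, rng=rng)
        results[name] = _subset_acc(cv.predicted, choices)
        null = {"correct": [], "error": []}
        for _ in range(n_shuffles):
            y_s = rng.permutation(choices)
            cv_s = predict_mouse_choice(df, y_s, kinds, k_folds=k_folds,
                                        folds=folds, rng=rng)
            acc = _subset_acc(cv_s.predicted, y_s)
            for key in null:
                null[key].append(acc[key])
        chances[name] = {
            key: tuple(np.percentile(v, [2.5, 97.5])) for key, v in null.items()
        }
    return DissociationResult(
        sensory=results["sensory"], history=results["history"],
        sensory_chance=chances["sensory"], history_chance=chances["history"],
        n_correct=int(correct.sum()), n_error=int((~correct).sum()))


def touch_sequence_stats(
    episode_directions: Sequence[Sequence[str]],
) -> dict[str, float]:
    """Descriptive statistics of within-trial touch sequences.

    Returns the fraction of trials with at most three touches, the fraction
    of second touches matching the first in direction, and the fraction of
    third touches matching the second (NaN when no trial qualifies).
    """
    n_trials = len(episode_directions)
    if n_trials == 0:
        raise ValueError("no trials")
    at_most_3 = np.mean([len(d) <= 3 for d in episode_directions])
    second = [d[1] == d[0] for d in episode_directions if len(d) >= 2]
    third = [d[2] == d[1] for d in episode_directions if len(d) >= 3]
    return {
        "frac_at_most_3_touches": float(at_most_3),
        "frac_second_matches_first": float(np.mean(second)) if second else float("nan"),
        "frac_third_matches_second": float(np.mean(third)) if third else float("nan"),
    }


def choice_bias_test(choices: Sequence) -> tuple[float, float]:
    """χ² goodness-of-fit of choice counts against equal frequencies.

    Counts are taken over the three canonical choice labels (zero counts
    included).  Returns (statistic, p-value).
    """
    choices = np.asarray(choices, dtype=object)
    if len(choices) < 3:
        raise ValueError("need at least three choices")
    counts = np.array([(choices == c).sum() for c in LOCATIONS], dtype=float)
    res = stats.chisquare(counts)
    return float(res.statistic), float(res.pvalue)
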