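"""Maximum-a-posteriori (naive Bayes) classification of trial labels.

The classifier predicts a ternary label y (pole location, or mouse choice)
from R per-trial predictors x_1..x_R assumed conditionally independent given
y:

    P(y = k | x_1..x_R)  ∝  π(k) · ∏_j P(x_j | y = k)

with the prior π taken from training-set class frequencies, multinomial
conditionals for categorical predictors and Gaussian conditionals for
continuous ones.  The predicted label is the posterior argmax, with ties
broken by a fixed class order (posterior, middle, anterior).

Evaluation follows the standard protocol for this kind of trial-resolved
behavioral analysis: tenfold cross-validation with predictions concatenated
across folds, and a chance level obtained by shuffling the labels and
repeating the whole cross-validated fit (50 iterations by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .simulate import LOCATIONS

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierFit",
    "CVResult",
    "NullDistribution",
    "fit_map_classifier",
    "predict",
    "crossval_predict",
    "classifier_performance",
    "choice_consistency",
    "shuffle_chance",
    "predict_mouse_choice",
]

#: Floor for zero-frequency categorical cells (avoids −∞ log likelihoods
#: without materially moving MAP decisions).
PROB_FLOOR = 1e-9
#: Floor on Gaussian conditional SD, in predictor units.
SD_FLOOR = 1e-6
#: Fixed tie-break/class order where applicable.
CLASS_ORDER = LOCATIONS


def _ordered_classes(y: np.ndarray) -> list:
    uniq = list(pd.unique(y))
    known = [c for c in CLASS_ORDER if c in uniq]
    extra = sorted(c for c in uniq if c not in CLASS_ORDER)
    return known + extra


@dataclass
class ClassifierFit:
    """Fitted priors and per-predictor class conditionals."""

    classes: list
    priors: np.ndarray
    #: per predictor: {"kind": "categorical", "levels": [...], "table": K×L}
    #: or {"kind": "gaussian", "mean": K, "sd": K}
    conditionals: dict[str, dict]
    kinds: dict[str, str]


@dataclass
class CVResult:
    """Cross-validated predictions in original trial order."""

    predicted: np.ndarray
    fold: np.ndarray
    posteriors: np.ndarray
    classes: list


@dataclass
class NullDistribution:
    """Shuffle null of an evaluation metric."""

    values: np.ndarray
    mean: float = field(init=False)
    lo: float = field(init=False)
    hi: float = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mean = float(self.values.mean())
        self.lo = float(np.percentile(self.values, 2.5))
        self.hi = float(np.percentile(self.values, 97.5))


def fit_map_classifier(
    X: pd.DataFrame,
    y: Sequence,
    kinds: Mapping[str, str],
    levels: Mapping[str, Sequence] | None = None,
) -> ClassifierFit:
    """Fit priors and conditionals from a training set.

    ``kinds`` maps each predictor column to ``'categorical'`` or
    ``'continuous'``.  ``levels`` optionally fixes the category set of a
    categorical predictor (needed to align folds that may not see every
    level).  Priors are training-set class frequencies; categorical
    conditionals within-class level frequencies; Gaussian conditionals
    within-class sample mean and SD (floored at ``SD_FLOOR``).
    """
    y = np.asarray(y, dtype=object)
    if len(X) != len(y):
        raise ValueError("X and y lengths differ")
    if len(y) == 0:
        raise ValueError("empty training set")
    unknown = set(kinds) - set(X.columns)
    if unknown:
        raise KeyError(f"predictors not in X: {sorted(unknown)}")
    classes = _ordered_classes(y)
    masks = [y == c for c in classes]
    counts = np.array([m.sum() for m in masks], dtype=float)
    if np.any(counts == 0):
        raise ValueError("a class is absent from the training set")
    priors = counts / counts.sum()

    conditionals: dict[str, dict] = {}
    for col, kind in kinds.items():
        vals = X[col].to_numpy()
        if kind == "categorical":
            lv = list(levels[col]) if levels and col in levels \
                else list(pd.unique(vals))
            index = {v: i for i, v in enumerate(lv)}
            table = np.zeros((len(classes), len(lv)))
            for k, m in enumerate(masks):
                for v in vals[m]:
                    if v not in index:
                        raise ValueError(
                            f"value {v!r} of {col!r} outside declared levels")
                    table[k, index[v]] += 1
                table[k] /= table[k].sum()
            conditionals[col] = {"kind": "categorical", "levels": lv,
                                 "table": table}
        elif kind == "continuous":
            x = vals.astype(float)
            if np.isnan(x).any():
                raise ValueError(f"missing values in continuous predictor {col!r}")
            mean = np.array([x[m].mean() for m in masks])
            sd = np.array([x[m].std(ddof=1) if m.sum() > 1 else 0.0
                           for m in masks])
            if np.any(sd < SD_FLOOR):
                logger.info("variance floor applied to predictor %r", col)
                sd = np.maximum(sd, SD_FLOOR)
            conditionals[col] = {"kind": "gaussian", "mean": mean, "sd": sd}
        else:
            raise ValueError(f"unknown predictor kind {kind!r} for {col!r}")
    return ClassifierFit(classes=classes, priors=priors,
                         conditionals=conditionals, kinds=dict(kinds))


def predict(fit: ClassifierFit, X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """MAP labels and normalized per-class posteriors for new trials.

    Computation is in the log domain; unseen categorical values contribute
    the floor probability.  Missing values raise (excluded first trials must
    be dropped by the caller before prediction).
    """
    T = len(X)
    K = len(fit.classes)
    logpost = np.tile(np.log(fit.priors), (T, 1))
    for col, cond in fit.conditionals.items():
        vals = X[col].to_numpy()
        if cond["kind"] == "categorical":
            if pd.isna(vals).any():
                raise ValueError(f"missing value in predictor {col!r}")
            index = {v: i for i, v in enumerate(cond["levels"])}
            logtab = np.log(np.maximum(cond["table"], PROB_FLOOR))
            floor_col = np.full((K, 1), np.log(PROB_FLOOR))
            logtab = np.hstack([logtab, floor_col])
            codes = np.array([index.get(v, len(index)) for v in vals])
            logpost += logtab[:, codes].T
        else:
            x = vals.astype(float)
            if np.isnan(x).any():
                raise ValueError(f"missing value in predictor {col!r}")
            mean, sd = cond["mean"], cond["sd"]
            ll = (-0.5 * ((x[:, None] - mean[None, :]) / sd[None, :]) ** 2
                  - np.log(sd[None, :]) - 0.5 * np.log(2 * np.pi))
            logpost += ll
    post = np.exp(logpost - logsumexp(logpost, axis=1, keepdims=True))
    # ties (within numerical tolerance) go to the earliest class in the
    # fixed class order, independent of log- vs linear-domain rounding
    near_max = post >= post.max(axis=1, keepdims=True) * (1.0 - 1e-9)
    winners = np.argmax(near_max, axis=1)
    labels = np.array([fit.classes[k] for k in winners], dtype=object)
    return labels, post


def _make_folds(T: int, k_folds: int, rng: np.random.Generator) -> np.ndarray:
    perm = rng.permutation(T)
    fold = np.empty(T, dtype=int)
    for f, idx in enumerate(np.array_split(perm, k_folds)):
        fold[idx] = f
    return fold


def _global_levels(X: pd.DataFrame, kinds: Mapping[str, str]) -> dict[str, list]:
    return {c: list(pd.unique(X[c].to_numpy()))
            for c, k in kinds.items() if k == "categorical"}


def crossval_predict(
    X: pd.DataFrame,
    y: Sequence,
    kinds: Mapping[str, str],
    k_folds: int = 10,
    rng: np.random.Generator | None = None,
    folds: np.ndarray | None = None,
    max_retries: int = 50,
) -> CVResult:
    """K-fold cross-validated MAP predictions, concatenated in trial order.

    Trials are randomly allocated to folds (sizes differ by at most one).  A
    partition leaving any class absent from some training split is resampled
    up to ``max_retries`` times.  Passing ``folds`` pins the assignment,
    e.g. to share folds between two classifiers.
    """
    y = np.asarray(y, dtype=object)
    T = len(y)
    if T < k_folds:
        raise ValueError("fewer trials than folds")
    if rng is None:
        rng = np.random.default_rng()
    levels = _global_levels(X, kinds)
    classes = set(pd.unique(y))

    if folds is not None:
        candidates = [np.asarray(folds)]
    else:
        candidates = None

    attempt = 0
    while True:
        fold = candidates[0] if candidates else _make_folds(T, k_folds, rng)
        ok = all(classes <= set(y[fold != f]) for f in range(k_folds))
        if ok:
            break
        attempt += 1
        if candidates or attempt > max_retries:
            raise ValueError(
                "could not build folds with every class in every training split")

    fit0 = None
    predicted = np.empty(T, dtype=object)
    posteriors = None
    class_list = _ordered_classes(y)
    for f in range(k_folds):
        test = fold == f
        fit = fit_map_classifier(X[~test], y[~test], kinds, levels=levels)
        fit0 = fit0 or fit
        labels, post = predict(fit, X[test])
        predicted[test] = labels
        if posteriors is None:
            posteriors = np.full((T, len(fit.classes)), np.nan)
        # class order is deterministic given the full label set, so columns align
        posteriors[test] = post
    return CVResult(predicted=predicted, fold=fold, posteriors=posteriors,
                    classes=class_list)


def classifier_performance(predicted: Sequence, true: Sequence) -> float:
    """Fraction of trials whose label was predicted correctly."""
    predicted = np.asarray(predicted, dtype=object)
    true = np.asarray(true, dtype=object)
    if len(predicted) != len(true):
        raise ValueError("length mismatch")
    if len(true) == 0:
        raise ValueError("empty input")
    return float(np.mean(predicted == true))


def choice_consistency(
    predicted_locations: Sequence,
    mouse_choices: Sequence,
    mapping: Mapping[str, str] | None = None,
) -> float:
    """Fraction of trials where the classifier's implied choice (via the
    location→correct-choice mapping) equals the mouse's choice."""
    if mapping is None:
        mapping = {loc: loc for loc in LOCATIONS}
    implied = np.array([mapping[p] for p in predicted_locations], dtype=object)
    return classifier_performance(implied, mouse_choices)


def shuffle_chance(
    X: pd.DataFrame,
    y: Sequence,
    kinds: Mapping[str, str],
    metric: Callable[[np.ndarray, np.ndarray], float] | None = None,
    iters: int = 50,
    k_folds: int = 10,
    rng: np.random.Generator | None = None,
    folds: np.ndarray | None = None,
) -> NullDistribution:
    """Chance level of a cross-validated metric by label shuffling.

    Each iteration permutes ``y`` relative to ``X``, reruns the full
    cross-validation, and records ``metric(predicted, y_shuffled)`` (default:
    :func:`classifier_performance`).  To calibrate choice consistency, pass a
    metric closure that compares predictions against the unshuffled choices.
    """
    if iters < 2:
        raise ValueError("need at least 2 shuffle iterations")
    if rng is None:
        rng = np.random.default_rng()
    if metric is None:
        metric = classifier_performance
    y = np.asarray(y, dtype=object)
    vals = np.empty(iters)
    for i in range(iters):
        y_s = rng.permutation(y)
        cv = crossval_predict(X, y_s, kinds, k_folds=k_folds, rng=rng,
                              folds=folds)
        vals[i] = metric(cv.predicted, y_s)
    return NullDistribution(values=vals)


def predict_mouse_choice(
    X: pd.DataFrame,
    choices: Sequence,
    kinds: Mapping[str, str],
    k_folds: int = 10,
    rng: np.random.Generator | None = None,
    folds: np.ndarray | None = None,
) -> CVResult:
    """Cross-validated prediction of the mouse's choice (rather than the
    pole location); same protocol as :func:`crossval_predict`."""
    return crossval_predict(X, choices, kinds, k_folds=k_folds, rng=rng,
                            folds=folds)
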