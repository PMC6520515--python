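"""End-to-end orchestration: simulate → extract → classify → behavior → report.

Each stage reads and writes plain CSV/JSON artifacts in a run directory so
stages can be rerun independently; :func:`analyze_cohort` offers the same
computation in memory for programmatic use.  All randomness derives from one
root seed through :class:`numpy.random.SeedSequence` spawn keys, so a config
with a fixed seed reproduces every artifact byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as bhv
from . import classifier as clf
from . import features as feat
from .simulate import LOCATIONS, BehaviorPolicy, SimConfig, generate_session

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "load_config",
    "run_simulate",
    "run_extract",
    "run_classify",
    "run_behavior",
    "run_report",
    "run_all",
    "analyze_cohort",
    "CLASSIFIER_SPECS",
]

#: The four classifiers compared throughout: predictor kinds by name.
CLASSIFIER_SPECS: dict[str, dict[str, str]] = {
    "pat": {"pat": "categorical"},
    "touch_type": {"touch_type": "categorical"},
    "dkappa95_touch_type": {"touch_type": "categorical",
                            "dkappa95": "continuous"},
    "previous_choice": {"prev_choice_type": "categorical"},
}

_STAGE_KEY = {"simulate": 0, "extract": 1, "classify": 2, "behavior": 3}

PREDICTOR_COLUMNS = (
    "session_id", "trial_idx", "pole_location", "choice", "correct",
    "pat", "touch_type", "dkappa95", "prev_choice_type", "n_touches",
    "episode_directions", "usable",
)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (see ``load_config`` for the TOML
    file layout)."""

    seed: int
    n_mice: int = 5
    outdir: Path = Path("runs")
    sim: SimConfig = field(default_factory=lambda: SimConfig(n_trials=760))
    policy: BehaviorPolicy = field(default_factory=BehaviorPolicy)
    dist_threshold: float = 0.5
    band_hz: tuple[float, float] = feat.DEFAULT_BAND
    k_folds: int = 10
    cv_shuffles: int = 50
    behavior_shuffles: int = 10_000

    def config_hash(self) -> str:
        # hash the scientific configuration only, not where it is written
        payload = _as_jsonable(self)
        payload.pop("outdir", None)
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def rng(self, stage: str, mouse: int = 0) -> np.random.Generator:
        ss = np.random.SeedSequence(self.seed,
                                    spawn_key=(_STAGE_KEY[stage], mouse))
        return np.random.default_rng(ss)


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v)
                for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def load_config(path: str | Path, seed: int | None = None,
                outdir: str | Path | None = None) -> RunConfig:
    """Read a TOML run configuration.

    Layout::

        [run]            # seed (mandatory), n_mice, outdir
        [sim]            # scalar SimConfig overrides (n_trials, whisk_freq, ...)
        [policy]         # p_perseverate, sensory_noise
        [features]       # dist_threshold, band_low, band_high
        [classifier]     # k_folds, shuffle_iters
        [analysis]       # n_shuffles

    ``seed``/``outdir`` arguments override the file.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    run = raw.get("run", {})
    if seed is None:
        if "seed" not in run:
            raise ValueError("config must set run.seed")
        seed = int(run["seed"])
    sim_kwargs = dict(raw.get("sim", {}))
    for key in ("location_probs", "touch_count_probs"):
        if key in sim_kwargs:
            sim_kwargs[key] = tuple(sim_kwargs[key])
    sim = SimConfig(**sim_kwargs)
    pol_kwargs = dict(raw.get("policy", {}))
    policy = BehaviorPolicy(**pol_kwargs)
    featcfg = raw.get("features", {})
    clfcfg = raw.get("classifier", {})
    ana = raw.get("analysis", {})
    return RunConfig(
        seed=seed,
        n_mice=int(run.get("n_mice", 5)),
        outdir=Path(outdir if outdir is not None else run.get("outdir", "runs")),
        sim=sim,
        policy=policy,
        dist_threshold=float(featcfg.get("dist_threshold", 0.5)),
        band_hz=(float(featcfg.get("band_low", feat.DEFAULT_BAND[0])),
                 float(featcfg.get("band_high", feat.DEFAULT_BAND[1]))),
        k_folds=int(clfcfg.get("k_folds", 10)),
        cv_shuffles=int(clfcfg.get("shuffle_iters", 50)),
        behavior_shuffles=int(ana.get("n_shuffles", 10_000)),
    )


def _mouse_ids(cfg: RunConfig) -> list[str]:
    return [f"mouse{m:02d}" for m in range(cfg.n_mice)]


def _write_json(path: Path, payload: dict, cfg: RunConfig) -> None:
    payload = dict(payload)
    payload["config_hash"] = cfg.config_hash()
    payload["seed"] = cfg.seed
    path.write_text(json.dumps(_as_jsonable(payload), sort_keys=True,
                               indent=1) + "\n")


def _read_csv(path: Path, required: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path.name}: missing required column(s): {', '.join(missing)}")
    return df


# ---------------------------------------------------------------- stages

def run_simulate(cfg: RunConfig) -> None:
    """Generate the cohort and write trials.csv plus per-mouse frame CSVs."""
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    all_trials = []
    for m, sid in enumerate(_mouse_ids(cfg)):
        rng = cfg.rng("simulate", m)
        data = generate_session(cfg.sim, cfg.policy, rng, session_id=sid)
        all_trials.append(data.trials)
        data.frames.to_csv(cfg.outdir / f"frames_{sid}.csv", index=False,
                           float_format="%.6f")
    trials = pd.concat(all_trials, ignore_index=True)
    trials.to_csv(cfg.outdir / "trials.csv", index=False)
    logger.info("simulate: %d mice × %d trials in %.1fs",
                cfg.n_mice, cfg.sim.n_trials, time.perf_counter() - t0)


def run_extract(cfg: RunConfig) -> None:
    """Extract per-trial predictors from the frame CSVs."""
    t0 = time.perf_counter()
    trials = _read_csv(cfg.outdir / "trials.csv",
                       ("session_id", "trial_idx", "pole_location", "choice",
                        "correct"))
    tables = []
    for sid in _mouse_ids(cfg):
        frames = _read_csv(cfg.outdir / f"frames_{sid}.csv",
                           ("session_id", "trial_idx", "t_ms", "angle_deg",
                            "kappa_per_mm", "pole_dist", "quality"))
        feats = feat.extract_session_features(frames, cfg.dist_threshold,
                                              cfg.band_hz)
        sub = trials[trials["session_id"] == sid].reset_index(drop=True)
        tables.append(feat.build_predictor_table(sub, feats))
    pred = pd.concat(tables, ignore_index=True)
    n_excluded = int((~pred["usable"]).sum())
    pred = pred.copy()
    pred["episode_directions"] = pred["episode_directions"].map(";".join)
    pred[list(PREDICTOR_COLUMNS)].to_csv(cfg.outdir / "predictors.csv",
                                         index=False)
    logger.info("extract: %d trials (%d excluded as unusable) in %.1fs",
                len(pred), n_excluded, time.perf_counter() - t0)


def _load_predictors(cfg: RunConfig) -> pd.DataFrame:
    pred = _read_csv(cfg.outdir / "predictors.csv", PREDICTOR_COLUMNS)
    pred["episode_directions"] = pred["episode_directions"].fillna("").map(
        lambda s: [d for d in s.split(";") if d])
    pred["usable"] = pred["usable"].astype(bool)
    return pred


def _classify_one(pred: pd.DataFrame, name: str, kinds: dict[str, str],
                  cfg: RunConfig, rng: np.random.Generator) -> dict:
    df = pred[pred["usable"]].reset_index(drop=True)
    if "prev_choice_type" in kinds:
        df = df[df["prev_choice_type"].notna()].reset_index(drop=True)
    y = df["pole_location"].to_numpy(dtype=object)
    choices = df["choice"].to_numpy(dtype=object)
    cv = clf.crossval_predict(df, y, kinds, k_folds=cfg.k_folds, rng=rng)
    perf = clf.classifier_performance(cv.predicted, y)
    cons = clf.choice_consistency(cv.predicted, choices)
    perf_null = clf.shuffle_chance(df, y, kinds, iters=cfg.cv_shuffles,
                                   k_folds=cfg.k_folds, rng=rng)
    cons_null = clf.shuffle_chance(
        df, y, kinds,
        metric=lambda p, _: clf.choice_consistency(p, choices),
        iters=cfg.cv_shuffles, k_folds=cfg.k_folds, rng=rng)
    return {
        "performance": perf,
        "consistency": cons,
        "performance_chance_ci": [perf_null.lo, perf_null.hi],
        "consistency_chance_ci": [cons_null.lo, cons_null.hi],
        "performance_above_chance": perf > perf_null.hi,
        "consistency_above_chance": cons > cons_null.hi,
        "n_trials": len(df),
    }


def run_classify(cfg: RunConfig) -> None:
    """Cross-validated classifiers (PAT, touch type, Δκ95+touch type,
    previous choice) per mouse, with 50-iteration shuffle chance."""
    t0 = time.perf_counter()
    pred = _load_predictors(cfg)
    out: dict = {"per_mouse": {}, "mean": {}}
    for m, sid in enumerate(_mouse_ids(cfg)):
        rng = cfg.rng("classify", m)
        sub = pred[pred["session_id"] == sid].reset_index(drop=True)
        out["per_mouse"][sid] = {
            name: _classify_one(sub, name, kinds, cfg, rng)
            for name, kinds in CLASSIFIER_SPECS.items()
        }
    for name in CLASSIFIER_SPECS:
        for metric in ("performance", "consistency"):
            vals = [out["per_mouse"][sid][name][metric]
                    for sid in _mouse_ids(cfg)]
            out["mean"].setdefault(name, {})[metric] = float(np.mean(vals))
            out["mean"][name][f"{metric}_sd"] = float(np.std(vals, ddof=1)) \
                if len(vals) > 1 else 0.0
    _write_json(cfg.outdir / "classify.json", out, cfg)
    logger.info("classify: done in %.1fs", time.perf_counter() - t0)


def run_behavior(cfg: RunConfig) -> None:
    """Behavioral statistics per mouse: performance vs chance,
    perseveration by subset, correct/error dissociation, touch sequences."""
    t0 = time.perf_counter()
    pred = _load_predictors(cfg)
    out: dict = {"per_mouse": {}, "mean": {}}
    for m, sid in enumerate(_mouse_ids(cfg)):
        rng = cfg.rng("behavior", m)
        sub = pred[pred["session_id"] == sid].reset_index(drop=True)
        summary = bhv.task_performance(sub, cfg.behavior_shuffles, rng)
        choices = sub["choice"].to_numpy(dtype=object)
        correct = sub["correct"].to_numpy(dtype=int) == 1
        pers = {
            "all": bhv.perseveration(choices, None, cfg.behavior_shuffles, rng),
            "correct": bhv.perseveration(choices, correct,
                                         cfg.behavior_shuffles, rng),
            "error": bhv.perseveration(choices, ~correct,
                                       cfg.behavior_shuffles, rng),
        }
        diss = bhv.dissociation_analysis(sub, rng, cfg.k_folds,
                                         cfg.cv_shuffles)
        stat, pval = bhv.choice_bias_test(choices)
        touched = [d for d in sub["episode_directions"] if d]
        out["per_mouse"][sid] = {
            "performance": summary.performance,
            "per_location": summary.per_location,
            "chance_ci": [summary.chance_lo, summary.chance_hi],
            "above_chance": summary.above_chance,
            "perseveration": {
                k: {"probability": v.probability,
                    "chance_ci": [v.chance_lo, v.chance_hi],
                    "above_chance": v.above_chance, "n": v.n}
                for k, v in pers.items()
            },
            "perseveration_by_previous_outcome":
                bhv.perseveration_by_previous_outcome(sub),
            "dissociation": {
                "sensory": diss.sensory, "history": diss.history,
                "sensory_chance": diss.sensory_chance,
                "history_chance": diss.history_chance,
                "n_correct": diss.n_correct, "n_error": diss.n_error,
            },
            "choice_bias": {"chi2": stat, "p": pval},
            "touch_sequences": bhv.touch_sequence_stats(touched)
            if touched else None,
            "n_trials": summary.n_trials,
        }
    ids = _mouse_ids(cfg)
    out["mean"]["performance"] = float(np.mean(
        [out["per_mouse"][s]["performance"] for s in ids]))
    for k in ("all", "correct", "error"):
        out["mean"][f"perseveration_{k}"] = float(np.mean(
            [out["per_mouse"][s]["perseveration"][k]["probability"]
             for s in ids]))
    for side in ("sensory", "history"):
        for subset in ("correct", "error"):
            out["mean"][f"{side}_{subset}"] = float(np.mean(
                [out["per_mouse"][s]["dissociation"][side][subset]
                 for s in ids]))
    _write_json(cfg.outdir / "behavior.json", out, cfg)
    logger.info("behavior: done in %.1fs", time.perf_counter() - t0)


def run_report(cfg: RunConfig) -> None:
    """Merge the classify and behavior artifacts into one report."""
    classify = json.loads((cfg.outdir / "classify.json").read_text())
    behavior = json.loads((cfg.outdir / "behavior.json").read_text())
    report = {"classifiers": classify, "behavior": behavior}
    _write_json(cfg.outdir / "report.json", report, cfg)

    lines = [
        "whiskmap run report",
        f"seed={cfg.seed}  config_hash={cfg.config_hash()}",
        f"mice={cfg.n_mice}  trials/mouse={cfg.sim.n_trials}",
        "",
        "classifier performance / choice consistency (mean across mice):",
    ]
    for name in CLASSIFIER_SPECS:
        m = classify["mean"][name]
        lines.append(f"  {name:22s} {m['performance']:.3f} ± "
                     f"{m['performance_sd']:.3f} / {m['consistency']:.3f}")
    b = behavior["mean"]
    lines += [
        "",
        f"mouse performance: {b['performance']:.3f}",
        "perseveration all/correct/error: "
        f"{b['perseveration_all']:.3f} / {b['perseveration_correct']:.3f} / "
        f"{b['perseveration_error']:.3f}",
        "choice prediction on error trials, sensory vs history: "
        f"{b['sensory_error']:.3f} vs {b['history_error']:.3f}",
        "choice prediction on correct trials, sensory vs history: "
        f"{b['sensory_correct']:.3f} vs {b['history_correct']:.3f}",
    ]
    (cfg.outdir / "report.txt").write_text("\n".join(lines) + "\n")


def run_all(cfg: RunConfig) -> None:
    run_simulate(cfg)
    run_extract(cfg)
    run_classify(cfg)
    run_behavior(cfg)
    run_report(cfg)


# ------------------------------------------------------- in-memory variant

def analyze_cohort(cfg: RunConfig) -> dict:
    """Simulate, extract and analyze a cohort fully in memory.

    Returns ``{"per_mouse": {...}, "mean": {...}}`` with, per mouse, the four
    classifier results, behavioral statistics and the dissociation —
    equivalent to the CSV pipeline without disk round-trips.
    """
    out: dict = {"per_mouse": {}, "mean": {}}
    for m, sid in enumerate(_mouse_ids(cfg)):
        rng = cfg.rng("simulate", m)
        data = generate_session(cfg.sim, cfg.policy, rng, session_id=sid)
        feats = feat.extract_session_features(
            data.frames, cfg.dist_threshold, cfg.band_hz)
        pred = feat.build_predictor_table(data.trials, feats)

        rng_c = cfg.rng("classify", m)
        mouse: dict = {"classifiers": {}}
        for name, kinds in CLASSIFIER_SPECS.items():
            mouse["classifiers"][name] = _classify_one(
                pred, name, kinds, cfg, rng_c)

        rng_b = cfg.rng("behavior", m)
        summary = bhv.task_performance(pred, cfg.behavior_shuffles, rng_b)
        choices = pred["choice"].to_numpy(dtype=object)
        correct = pred["correct"].to_numpy(dtype=int) == 1
        mouse["performance"] = summary.performance
        mouse["touch_by_location"] = {
            loc: float(pred.loc[pred["pole_location"] == loc, "pat"].mean())
            for loc in LOCATIONS
        }
        mouse["perseveration"] = {
            "all": bhv.perseveration(choices, None, cfg.behavior_shuffles,
                                     rng_b).probability,
            "correct": bhv.perseveration(choices, correct,
                                         cfg.behavior_shuffles,
                                         rng_b).probability,
            "error": bhv.perseveration(choices, ~correct,
                                       cfg.behavior_shuffles,
                                       rng_b).probability,
        }
        diss = bhv.dissociation_analysis(pred, rng_b, cfg.k_folds,
                                         cfg.cv_shuffles)
        mouse["dissociation"] = {"sensory": diss.sensory,
                                 "history": diss.history}
        mouse["n_trials"] = len(pred)
        out["per_mouse"][sid] = mouse

    ids = _mouse_ids(cfg)
    mean: dict = {}
    for name in CLASSIFIER_SPECS:
        for metric in ("performance", "consistency"):
            mean[f"{name}_{metric}"] = float(np.mean(
                [out["per_mouse"][s]["classifiers"][name][metric]
                 for s in ids]))
    mean["performance"] = float(np.mean(
        [out["per_mouse"][s]["performance"] for s in ids]))
    for k in ("all", "correct", "error"):
        mean[f"perseveration_{k}"] = float(np.mean(
            [out["per_mouse"][s]["perseveration"][k] for s in ids]))
    for side in ("sensory", "history"):
        for subset in ("correct", "error"):
            mean[f"{side}_{subset}"] = float(np.mean(
                [out["per_mouse"][s]["dissociation"][side][subset]
                 for s in ids]))
    for loc in LOCATIONS:
        mean[f"touch_prob_{loc}"] = float(np.mean(
            [out["per_mouse"][s]["touch_by_location"][loc] for s in ids]))
    out["mean"] = mean
    return out
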