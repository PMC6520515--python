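"""Mechanosensory predictors from tracked whisker time series.

Starting from per-trial 1 kHz traces of whisker angle θ, curvature κ and
whisker–pole distance, this module derives the per-trial predictor variables
used by the classifiers:

* **PAT** — presence/absence of touch (binary);
* **touch type** — direction of the first touch, protraction / retraction /
  none, from the Hilbert phase of the band-passed whisker angle;
* **Δκ95** — the 5th or 95th percentile (whichever is larger in magnitude) of
  baseline-subtracted curvature over the first touch episode; zero by
  definition when no touch occurred;
* **previous choice type** — the previous trial's choice combined with its
  correctness (six levels).

Touch episodes are maximal runs of frames whose whisker–pole distance falls
below a threshold.  Frames that failed tracking quality control are flagged
``dropped``; isolated drops are repaired by linear interpolation, longer runs
are left unresolved and split any touch episode they interrupt.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, hilbert, sosfiltfilt

logger = logging.getLogger(__name__)

__all__ = [
    "TouchEpisode",
    "UnusableTrialError",
    "fill_isolated_gaps",
    "detect_touch_episodes",
    "whisking_phase",
    "classify_touch_type",
    "delta_kappa_95",
    "whisking_amplitude",
    "extract_trial_features",
    "extract_session_features",
    "build_predictor_table",
]

#: Default band (Hz) isolating the whisking rhythm for phase/amplitude.
DEFAULT_BAND = (4.0, 30.0)
#: Frames of pre-touch curvature used for the Δκ baseline.
BASELINE_FRAMES = 6


class UnusableTrialError(ValueError):
    """Raised when a trial cannot yield a valid Δκ95 (e.g. the whole
    pre-touch baseline window was dropped)."""


@dataclass
class TouchEpisode:
    """Inclusive frame bounds of one contiguous whisker–pole contact."""

    start_ms: int
    end_ms: int
    direction: str | None = None
    is_first: bool = False

    def __post_init__(self) -> None:
        if self.end_ms < self.start_ms:
            raise ValueError("episode end precedes start")


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise KeyError(f"frame series missing column(s): {', '.join(missing)}")


def fill_isolated_gaps(series: pd.DataFrame) -> pd.DataFrame:
    """Repair single dropped frames by interpolating θ and κ from neighbours.

    Only dropped frames flanked on both sides by ok frames are filled (and
    reflagged ok); runs of two or more dropped frames are left untouched.
    """
    _require_columns(series, ("angle_deg", "kappa_per_mm", "quality"))
    dropped = (series["quality"].to_numpy() == "dropped")
    if not dropped.any():
        return series
    out = series.copy()
    n = len(dropped)
    prev_ok = np.concatenate(([False], ~dropped[:-1]))
    next_ok = np.concatenate((~dropped[1:], [False]))
    isolated = dropped & prev_ok & next_ok
    idx = np.flatnonzero(isolated)
    for col in ("angle_deg", "kappa_per_mm", "pole_dist"):
        if col not in out.columns:
            continue
        v = out[col].to_numpy(dtype=float, copy=True)
        v[idx] = 0.5 * (v[idx - 1] + v[idx + 1])
        out[col] = v
    q = out["quality"].to_numpy(copy=True)
    q[idx] = "ok"
    out["quality"] = q
    return out


def detect_touch_episodes(
    series: pd.DataFrame, dist_threshold: float
) -> list[TouchEpisode]:
    """Maximal runs of frames with whisker–pole distance below threshold.

    Dropped frames (distance unresolved) split any run they interrupt; a
    warning is logged when that happens.  The earliest episode is flagged
    ``is_first``.
    """
    if dist_threshold <= 0:
        raise ValueError("dist_threshold must be positive")
    _require_columns(series, ("pole_dist", "quality", "t_ms"))
    dist = series["pole_dist"].to_numpy(dtype=float)
    dropped = series["quality"].to_numpy() == "dropped"
    with np.errstate(invalid="ignore"):
        below = (dist < dist_threshold) & ~dropped
    if not below.any():
        return []
    t = series["t_ms"].to_numpy()
    padded = np.concatenate(([False], below, [False]))
    d = np.diff(padded.astype(int))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    episodes = [
        TouchEpisode(start_ms=int(t[a]), end_ms=int(t[b]), is_first=(k == 0))
        for k, (a, b) in enumerate(zip(starts, ends))
    ]
    # a dropped frame wedged between two below-threshold frames split a run
    for a, b in zip(ends[:-1], starts[1:]):
        if np.all(dropped[a + 1:b]):
            logger.warning(
                "touch episode split at unresolved (dropped) frames "
                "%d–%d", int(t[a + 1]), int(t[b - 1]))
    return episodes


def _bandpassed(angle: np.ndarray, band: tuple[float, float], fs: float) -> np.ndarray:
    low, high = band
    if not (0.0 < low < high < fs / 2.0):
        raise ValueError("band must satisfy 0 < low < high < Nyquist")
    if len(angle) < 3.0 * fs / low:
        raise ValueError(
            "series shorter than 3 cycles of the low band edge")
    x = np.asarray(angle, dtype=float)
    # interpolate any unresolved frames so the filter sees a finite signal
    bad = ~np.isfinite(x)
    if bad.any():
        good = np.flatnonzero(~bad)
        if good.size == 0:
            raise ValueError("angle series has no finite samples")
        x = x.copy()
        x[bad] = np.interp(np.flatnonzero(bad), good, x[good])
    sos = butter(2, band, btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, x - x.mean())


def whisking_phase(
    angle: np.ndarray,
    band_hz: tuple[float, float] = DEFAULT_BAND,
    fs: float = 1000.0,
) -> np.ndarray:
    """Per-frame whisking phase in (−π, π] from the analytic signal.

    The angle is mean-removed and band-passed (zero-phase) before the Hilbert
    transform.  Convention: phase in [−π, 0) is protraction (angle rising),
    [0, π) is retraction; a rising zero crossing sits at −π/2.
    """
    return np.angle(hilbert(_bandpassed(angle, band_hz, fs)))


def whisking_amplitude(
    angle: np.ndarray,
    band_hz: tuple[float, float] = DEFAULT_BAND,
    fs: float = 1000.0,
) -> np.ndarray:
    """Per-frame whisking amplitude (degrees): envelope of the analytic
    signal of the band-passed angle."""
    return np.abs(hilbert(_bandpassed(angle, band_hz, fs)))


def classify_touch_type(
    episodes: list[TouchEpisode],
    phase: np.ndarray,
    quality: np.ndarray | None = None,
) -> tuple[str, list[TouchEpisode]]:
    """Label each episode by the whisking phase at its start frame.

    Phase strictly inside (−π, 0) is protraction; anything else (including
    exactly 0 or ±π) is retraction.  If the start frame is dropped, the first
    ok frame of the episode is used instead.  Returns the trial-level touch
    type — the direction of the first episode, or ``'none'`` — along with the
    labeled episodes.
    """
    labeled = []
    for ep in episodes:
        f = ep.start_ms
        if quality is not None:
            while f <= ep.end_ms and quality[f] == "dropped":
                f += 1
            if f > ep.end_ms:
                f = ep.start_ms  # entire episode dropped: fall back
        phi = phase[f]
        direction = "protraction" if (-np.pi < phi < 0.0) else "retraction"
        labeled.append(TouchEpisode(ep.start_ms, ep.end_ms, direction, ep.is_first))
    touch_type = labeled[0].direction if labeled else "none"
    return touch_type, labeled


def delta_kappa_95(
    series: pd.DataFrame, first_episode: TouchEpisode | None
) -> float:
    """Δκ95: extreme curvature change during the first touch episode.

    Baseline is the median κ over the 6 frames immediately preceding touch
    onset (ok frames only).  Over the episode's ok frames, Δκ(f) = κ(f) −
    baseline; the returned value is whichever of the 5th or 95th percentile
    of {Δκ(f)} has the greater absolute value (ties go to the 95th,
    matching the protraction-positive sign convention).  Percentiles use
    linear interpolation between order statistics.  Returns 0.0 when there
    was no touch.

    Raises :class:`UnusableTrialError` if every baseline frame was dropped.
    """
    if first_episode is None:
        return 0.0
    _require_columns(series, ("kappa_per_mm", "quality", "t_ms"))
    t = series["t_ms"].to_numpy()
    kappa = series["kappa_per_mm"].to_numpy(dtype=float)
    ok = series["quality"].to_numpy() == "ok"
    start = int(np.searchsorted(t, first_episode.start_ms))
    end = int(np.searchsorted(t, first_episode.end_ms))
    base_lo = max(0, start - BASELINE_FRAMES)
    base_sel = ok[base_lo:start]
    base_vals = kappa[base_lo:start][base_sel]
    if base_vals.size == 0:
        raise UnusableTrialError(
            "all pre-touch baseline frames dropped; trial unusable")
    baseline = float(np.median(base_vals))
    ep_vals = kappa[start:end + 1][ok[start:end + 1]]
    if ep_vals.size == 0:
        raise UnusableTrialError("no resolved frames inside first touch")
    dk = ep_vals - baseline
    p5, p95 = np.percentile(dk, [5.0, 95.0])  # linear interpolation
    return float(p95) if abs(p95) >= abs(p5) else float(p5)


def extract_trial_features(
    series: pd.DataFrame,
    dist_threshold: float = 0.5,
    band_hz: tuple[float, float] = DEFAULT_BAND,
) -> dict:
    """All per-trial predictors from one trial's frame series.

    Returns a dict with keys ``pat``, ``touch_type``, ``dkappa95``,
    ``n_touches``, ``episode_directions`` and ``usable`` (False when the
    Δκ95 baseline was unrecoverable; such trials are excluded downstream).
    """
    series = fill_isolated_gaps(series)
    episodes = detect_touch_episodes(series, dist_threshold)
    if episodes:
        phase = whisking_phase(series["angle_deg"].to_numpy(), band_hz)
        touch_type, episodes = classify_touch_type(
            episodes, phase, series["quality"].to_numpy())
    else:
        touch_type = "none"
    first = next((ep for ep in episodes if ep.is_first), None)
    usable = True
    try:
        dk95 = delta_kappa_95(series, first)
    except UnusableTrialError:
        dk95 = np.nan
        usable = False
    return {
        "pat": int(bool(episodes)),
        "touch_type": touch_type,
        "dkappa95": dk95,
        "n_touches": len(episodes),
        "episode_directions": [ep.direction for ep in episodes],
        "usable": usable,
    }


def extract_session_features(
    frames: pd.DataFrame,
    dist_threshold: float = 0.5,
    band_hz: tuple[float, float] = DEFAULT_BAND,
) -> pd.DataFrame:
    """Per-trial features for every trial in a long-format frame table."""
    _require_columns(frames, ("session_id", "trial_idx", "t_ms", "angle_deg",
                              "kappa_per_mm", "pole_dist", "quality"))
    rows = []
    for (sid, tidx), grp in frames.groupby(["session_id", "trial_idx"], sort=True):
        feats = extract_trial_features(grp.reset_index(drop=True),
                                       dist_threshold, band_hz)
        feats["session_id"] = sid
        feats["trial_idx"] = tidx
        rows.append(feats)
    out = pd.DataFrame(rows)
    return out[["session_id", "trial_idx", "pat", "touch_type", "dkappa95",
                "n_touches", "episode_directions", "usable"]]


def build_predictor_table(
    trials: pd.DataFrame, features: pd.DataFrame
) -> pd.DataFrame:
    """Join trial records with features and derive the history predictor.

    Adds ``prev_choice_type`` — the previous trial's choice combined with its
    correctness, e.g. ``'middle_correct'`` — which is undefined (NA) on the
    first trial of each session.  Output carries the predictors alongside the
    label columns ``pole_location`` and ``choice``.
    """
    if len(trials) != len(features):
        raise ValueError(
            f"trial table ({len(trials)} rows) and features "
            f"({len(features)} rows) do not match")
    df = trials.merge(features, on=["session_id", "trial_idx"],
                      how="inner", validate="one_to_one")
    if len(df) != len(trials):
        raise ValueError("trial table and features index different trials")
    df = df.sort_values(["session_id", "trial_idx"]).reset_index(drop=True)
    # predictor invariant: no touch => no type => zero bending index
    no_touch = df["pat"] == 0
    bad = no_touch & ((df["touch_type"] != "none") | (df["dkappa95"] != 0.0))
    if bad.any():
        raise ValueError("predictor invariant violated: pat=0 rows must "
                         "have touch_type='none' and dkappa95=0")
    grp = df.groupby("session_id", sort=False)
    prev_choice = grp["choice"].shift(1)
    prev_correct = grp["correct"].shift(1)
    df["prev_choice_type"] = np.where(
        prev_choice.isna(), pd.NA,
        prev_choice.astype(str) + "_" +
        np.where(prev_correct == 1, "correct", "error"))
    return df
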