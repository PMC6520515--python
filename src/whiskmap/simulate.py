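"""Synthetic sessions for the three-choice whisker-guided pole localization task.

A head-fixed mouse palpates a vertical pole with a single whisker and reports
the pole's anterior–posterior position (posterior / middle / anterior) by
licking left, licking right, or withholding licks.  Choices are labeled by the
pole location for which they are correct, so choice and location share one
label set.

The generator emulates the statistical structure the downstream analysis
assumes rather than whisker biomechanics:

* pole locations follow a constrained pseudorandom ("AB") sequence with a cap
  on runs of the same location;
* the whisker angle is a set-point-centred sinusoid whose amplitude ramps up
  after pole onset (mice whisk little before the pole arrives);
* whisker–pole touches occur with a location-dependent probability, during
  protraction (angle rising) or retraction (angle falling) with
  location-dependent odds, and each touch adds a curvature transient whose
  peak is drawn from a Gaussian specific to (location, direction) — positive
  for protraction touches, negative for retraction touches;
* the mouse's choice mixes a perseverative branch (repeat the previous
  choice with probability ``p_perseverate``) with a sensory branch that
  reports the correct choice up to a lapse rate.

All randomness flows through a single :class:`numpy.random.Generator`, so a
seed reproduces a session byte for byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "LOCATIONS",
    "DIRECTIONS",
    "SimConfig",
    "BehaviorPolicy",
    "SessionData",
    "generate_pole_sequence",
    "synth_whisking_trace",
    "synth_contact",
    "generate_choice",
    "generate_session",
]

#: Canonical label order for pole locations (and, via the location→choice
#: mapping, for choices).  Also the classifier's tie-break order.
LOCATIONS: tuple[str, ...] = ("posterior", "middle", "anterior")
DIRECTIONS: tuple[str, ...] = ("protraction", "retraction")

#: Frame columns written by :func:`generate_session`.
FRAME_COLUMNS = (
    "session_id", "trial_idx", "t_ms", "angle_deg",
    "kappa_per_mm", "pole_dist", "quality",
)
TRIAL_COLUMNS = (
    "session_id", "trial_idx", "pole_location", "choice", "correct",
    "true_touch", "true_first_touch_dir",
)


def _default_touch_prob() -> dict[str, float]:
    # Probability of >=1 touch per trial by pole location.
    return {"posterior": 0.87, "middle": 0.93, "anterior": 0.46}


def _default_touch_dir_probs() -> dict[str, tuple[float, float]]:
    # (P(protraction), P(retraction)) of the first touch, given a touch.
    # Posterior poles are met on the backward sweep, middle/anterior on the
    # forward sweep.
    return {
        "posterior": (0.15, 0.85),
        "middle": (0.90, 0.10),
        "anterior": (0.95, 0.05),
    }


def _default_dkappa_params() -> dict[tuple[str, str], tuple[float, float]]:
    # (mean, sd) in 1/mm of the peak curvature change for each
    # (location, direction).  Free parameters of the simulation: within each
    # direction the means are separated by >=2 sd and |mean| >= 2 sd, so
    # the magnitude carries location information beyond direction alone.
    return {
        ("posterior", "protraction"): (0.008, 0.004),
        ("middle", "protraction"): (0.016, 0.004),
        ("anterior", "protraction"): (0.028, 0.004),
        ("posterior", "retraction"): (-0.028, 0.004),
        ("middle", "retraction"): (-0.016, 0.004),
        ("anterior", "retraction"): (-0.008, 0.004),
    }


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated session.

    Times are in ms on a fixed 1 kHz frame clock; angles in degrees with 0°
    along the anterior–posterior axis (nose to tail) and protraction =
    increasing angle; curvature in 1/mm.
    """

    n_trials: int = 179
    location_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    max_run: int = 3
    frame_rate: float = 1000.0
    trial_duration: int = 1500
    pole_onset: int = 500
    whisk_freq: float = 15.0
    amp_pre: float = 1.0
    amp_post: float = 15.0
    setpoint: float = 100.0
    ramp_ms: int = 100
    touch_prob: Mapping[str, float] = field(default_factory=_default_touch_prob)
    touch_dir_probs: Mapping[str, tuple[float, float]] = field(
        default_factory=_default_touch_dir_probs)
    dkappa_params: Mapping[tuple[str, str], tuple[float, float]] = field(
        default_factory=_default_dkappa_params)
    baseline_kappa: float = 0.002
    free_dist: float = 3.0
    touch_count_probs: tuple[float, ...] = (0.35, 0.25, 0.24, 0.10, 0.06)
    dir_persistence: float = 0.94
    noise_sd_angle: float = 0.5
    noise_sd_kappa: float = 0.001
    p_dropped: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.location_probs, float)
        if p.shape != (3,) or np.any(p < 0) or np.any(p > 1):
            raise ValueError("location_probs must be three probabilities")
        if not np.isclose(p.sum(), 1.0):
            raise ValueError("location_probs must sum to 1")
        if self.max_run < 1:
            raise ValueError("max_run must be >= 1")
        if not (self.amp_post > self.amp_pre >= 0):
            raise ValueError("require amp_post > amp_pre >= 0")
        if self.frame_rate != 1000.0:
            raise ValueError("frame clock is fixed at 1 kHz")
        if not (0 < self.pole_onset < self.trial_duration):
            raise ValueError("pole_onset must fall inside the trial")
        for name, val in (("touch_prob", self.touch_prob.values()),):
            if any(not (0 <= v <= 1) for v in val):
                raise ValueError(f"{name} entries must be probabilities")
        for loc, (ppro, pret) in self.touch_dir_probs.items():
            if not np.isclose(ppro + pret, 1.0):
                raise ValueError(f"touch_dir_probs[{loc!r}] must sum to 1")
        if not np.isclose(sum(self.touch_count_probs), 1.0):
            raise ValueError("touch_count_probs must sum to 1")

    @property
    def n_frames(self) -> int:
        return int(round(self.trial_duration * self.frame_rate / 1000.0))


@dataclass(frozen=True)
class BehaviorPolicy:
    """Choice policy mixing perseveration with sensory-guided responding.

    With probability ``p_perseverate`` the previous choice is repeated;
    otherwise the sensory branch reports ``mapping[pole_location]`` except
    with lapse probability ``sensory_noise``, where a uniformly random choice
    is made.  The first trial of a session is always sensory-guided.
    """

    p_perseverate: float = 0.25
    sensory_noise: float = 0.15
    mapping: Mapping[str, str] = field(
        default_factory=lambda: {loc: loc for loc in LOCATIONS})

    def __post_init__(self) -> None:
        if not (0 <= self.p_perseverate <= 1 and 0 <= self.sensory_noise <= 1):
            raise ValueError("policy probabilities must lie in [0, 1]")
        if sorted(self.mapping) != sorted(LOCATIONS) or \
                sorted(self.mapping.values()) != sorted(LOCATIONS):
            raise ValueError("mapping must be a bijection over the locations")


@dataclass
class SessionData:
    """One simulated session: trial table, frame store and ground truth."""

    trials: pd.DataFrame
    frames: pd.DataFrame
    #: per-trial ground truth: dict with keys 'intervals' (list of inclusive
    #: (start, end) frame pairs), 'directions', 'peaks' and 'first_dir'.
    truth: dict[int, dict]


def generate_pole_sequence(
    n_trials: int,
    location_probs: Sequence[float],
    max_run: int,
    rng: np.random.Generator,
) -> list[str]:
    """Constrained pseudorandom pole-location sequence (AB policy).

    Locations are drawn i.i.d. from ``location_probs`` except that a draw
    that would extend a run of identical locations past ``max_run`` is
    redrawn from the remaining locations (probabilities renormalized).
    """
    p = np.asarray(location_probs, float)
    if p.shape != (3,) or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError("location_probs must be a 3-vector summing to 1")
    if max_run < 1:
        raise ValueError("max_run must be >= 1")
    if np.count_nonzero(p) < 2 and n_trials > max_run:
        raise ValueError(
            "run constraint unsatisfiable: only one location has nonzero "
            f"probability but max_run={max_run} < n_trials={n_trials}")
    seq: list[int] = []
    run_loc, run_len = -1, 0
    for _ in range(n_trials):
        if run_len >= max_run:
            q = p.copy()
            q[run_loc] = 0.0
            q = q / q.sum()
        else:
            q = p
        k = int(rng.choice(3, p=q))
        if k == run_loc:
            run_len += 1
        else:
            run_loc, run_len = k, 1
        seq.append(k)
    return [LOCATIONS[k] for k in seq]


def synth_whisking_trace(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Whisker angle trace: set-point-centred sinusoid with amplitude ramp.

    θ(t) = setpoint + A(t)·cos(2π·f·t + φ₀) + N(0, noise_sd_angle), where
    A(t) is ``amp_pre`` before pole onset and ramps linearly to ``amp_post``
    over ``ramp_ms`` after onset.  φ₀ is uniform per trial.
    """
    n = config.n_frames
    t = np.arange(n, dtype=float)  # ms
    phi0 = rng.uniform(0.0, 2.0 * np.pi)
    ramp = np.clip((t - config.pole_onset) / max(config.ramp_ms, 1), 0.0, 1.0)
    amp = config.amp_pre + (config.amp_post - config.amp_pre) * ramp
    theta = config.setpoint + amp * np.cos(
        2.0 * np.pi * config.whisk_freq * t / 1000.0 + phi0)
    if config.noise_sd_angle > 0:
        theta = theta + rng.normal(0.0, config.noise_sd_angle, n)
    return theta


def _whisk_segments(angle: np.ndarray, config: SimConfig) -> list[tuple[int, int, str]]:
    """Monotone half-cycles of the whisk, from turning points of the trace.

    Returns (start, end, direction) triples restricted to after the amplitude
    ramp, direction 'protraction' for rising segments and 'retraction' for
    falling ones.  Works on the (possibly noisy) angle series itself so the
    contact synthesizer needs no access to the hidden oscillator phase.
    """
    n = len(angle)
    if config.noise_sd_angle > 0:
        win = min(21, n - (1 - n % 2))
        smooth = savgol_filter(angle, win, 3)
    else:
        smooth = angle
    start = config.pole_onset + config.ramp_ms
    if start >= n - 4:
        return []
    seg = smooth[start:]
    d = np.diff(seg)
    sign = np.sign(d)
    # turning points: indices where the derivative changes sign
    turns = np.flatnonzero(sign[:-1] * sign[1:] < 0) + 1
    bounds = np.concatenate(([0], turns, [len(seg) - 1]))
    out: list[tuple[int, int, str]] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a < 6:  # too short to host a touch
            continue
        direction = "protraction" if seg[b] > seg[a] else "retraction"
        out.append((start + int(a), start + int(b), direction))
    return out


def synth_contact(
    angle_series: np.ndarray,
    pole_location: str,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]], list[str], list[float], str]:
    """Whisker–pole distance and curvature consistent with the angle trace.

    With probability ``touch_prob[pole_location]`` the trial contains one or
    more touch episodes.  Each touch occupies the middle of a distinct whisk
    half-cycle whose direction is drawn from ``touch_dir_probs`` (first
    touch) or repeats the previous direction with probability
    ``dir_persistence`` (later touches).  During a touch the pole distance
    drops to zero and the curvature rises over a half-cosine bump to a peak
    drawn from the Gaussian of ``dkappa_params[(location, direction)]``, sign
    forced positive for protraction and negative for retraction.

    Returns ``(pole_dist, kappa, intervals, directions, peaks, first_dir)``
    with inclusive frame intervals; ``first_dir`` is ``'none'`` on no-touch
    trials.
    """
    n = len(angle_series)
    dist = np.full(n, config.free_dist, dtype=float)
    kappa = np.full(n, config.baseline_kappa, dtype=float)
    if config.noise_sd_kappa > 0:
        kappa += rng.normal(0.0, config.noise_sd_kappa, n)

    intervals: list[tuple[int, int]] = []
    directions: list[str] = []
    peaks: list[float] = []

    touched = rng.random() < config.touch_prob[pole_location]
    if touched:
        segments = _whisk_segments(angle_series, config)
        n_touch = 1 + int(rng.choice(len(config.touch_count_probs),
                                     p=config.touch_count_probs))
        p_pro, _ = config.touch_dir_probs[pole_location]
        want: list[str] = []
        for i in range(n_touch):
            if i == 0:
                d = "protraction" if rng.random() < p_pro else "retraction"
            else:
                same = rng.random() < config.dir_persistence
                d = want[-1] if same else _other(want[-1])
            want.append(d)
        seg_i = 0
        for d in want:
            while seg_i < len(segments) and segments[seg_i][2] != d:
                seg_i += 1
            if seg_i >= len(segments):
                break
            s, e, _ = segments[seg_i]
            seg_i += 1
            seg_len = e - s + 1
            dur = int(rng.integers(9, 22))
            dur = min(dur, seg_len - 2)
            if dur % 2 == 0:
                dur -= 1
            if dur < 5:
                continue
            mid = (s + e) // 2
            a = mid - dur // 2
            b = a + dur - 1
            mu, sd = config.dkappa_params[(pole_location, d)]
            peak = float(np.sign(mu) * abs(rng.normal(mu, sd)))
            # half-cosine rise and fall around a 3-frame plateau: holding the
            # peak makes the 95th-percentile bending statistic attain the
            # drawn peak exactly on noiseless data (episodes up to ~40 frames)
            r = (dur - 3) // 2
            u = (np.arange(r) + 1.0) / (r + 1.0)
            rise = (1.0 - np.cos(np.pi * u)) / 2.0
            bump = peak * np.concatenate([rise, np.ones(3), rise[::-1]])
            kappa[a:b + 1] += bump
            dist[a:b + 1] = 0.0
            intervals.append((a, b))
            directions.append(d)
            peaks.append(peak)

    first_dir = directions[0] if directions else "none"
    return dist, kappa, intervals, directions, peaks, first_dir


def _other(direction: str) -> str:
    return "retraction" if direction == "protraction" else "protraction"


def generate_choice(
    pole_location: str,
    previous_choice: str | None,
    policy: BehaviorPolicy,
    rng: np.random.Generator,
) -> str:
    """One choice under the perseveration/sensory mixture policy."""
    if previous_choice is not None and rng.random() < policy.p_perseverate:
        return previous_choice
    if rng.random() < policy.sensory_noise:
        return str(rng.choice(LOCATIONS))
    return policy.mapping[pole_location]


def generate_session(
    config: SimConfig,
    policy: BehaviorPolicy,
    rng: np.random.Generator | None = None,
    session_id: str = "s00",
    with_frames: bool = True,
) -> SessionData:
    """Simulate a full session.

    ``with_frames=False`` skips the frame-series synthesis and returns an
    empty frame table (useful for behavior-only simulations, where only the
    trial table matters).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)

    locations = generate_pole_sequence(
        config.n_trials, config.location_probs, config.max_run, rng)

    n = config.n_frames
    trial_rows = []
    frame_blocks = []
    truth: dict[int, dict] = {}
    prev_choice: str | None = None

    for i, loc in enumerate(locations):
        if with_frames:
            angle = synth_whisking_trace(config, rng)
            dist, kappa, intervals, dirs, peaks, first_dir = synth_contact(
                angle, loc, config, rng)
            quality = np.zeros(n, dtype=bool)  # True = dropped
            if config.p_dropped > 0:
                drop = np.flatnonzero(rng.random(n) < config.p_dropped)
                # keep drops isolated: discard any drop adjacent to an
                # earlier kept one
                kept: list[int] = []
                for j in drop:
                    if not kept or j - kept[-1] > 1:
                        kept.append(int(j))
                quality[kept] = True
                angle = angle.copy()
                kappa = kappa.copy()
                dist = dist.copy()
                angle[quality] = np.nan
                kappa[quality] = np.nan
                dist[quality] = np.nan
            frame_blocks.append((i, angle, kappa, dist, quality))
            truth[i] = {
                "intervals": intervals,
                "directions": dirs,
                "peaks": peaks,
                "first_dir": first_dir,
            }
            true_touch = int(bool(intervals))
        else:
            # behavior-only: draw touch occurrence so trial schema is complete
            true_touch = int(rng.random() < config.touch_prob[loc])
            first_dir = "none"
            truth[i] = {"intervals": [], "directions": [], "peaks": [],
                        "first_dir": "none"}

        choice = generate_choice(loc, prev_choice, policy, rng)
        prev_choice = choice
        trial_rows.append({
            "session_id": session_id,
            "trial_idx": i,
            "pole_location": loc,
            "choice": choice,
            "correct": int(choice == policy.mapping[loc]),
            "true_touch": true_touch,
            "true_first_touch_dir": first_dir,
        })

    trials = pd.DataFrame(trial_rows, columns=list(TRIAL_COLUMNS))

    if with_frames:
        t_ms = np.arange(n, dtype=int)
        frames = pd.DataFrame({
            "session_id": session_id,
            "trial_idx": np.repeat([b[0] for b in frame_blocks], n),
            "t_ms": np.tile(t_ms, len(frame_blocks)),
            "angle_deg": np.concatenate([b[1] for b in frame_blocks]),
            "kappa_per_mm": np.concatenate([b[2] for b in frame_blocks]),
            "pole_dist": np.concatenate([b[3] for b in frame_blocks]),
            "quality": np.where(
                np.concatenate([b[4] for b in frame_blocks]), "dropped", "ok"),
        })
    else:
        frames = pd.DataFrame(columns=list(FRAME_COLUMNS))

    return SessionData(trials=trials, frames=frames, truth=truth)


def noiseless(config: SimConfig) -> SimConfig:
    """Copy of ``config`` with all noise sources (and frame drops) off."""
    return dataclasses.replace(
        config, noise_sd_angle=0.0, noise_sd_kappa=0.0, p_dropped=0.0)
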