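"""Exercise evaluators: flexion counting, step-climb counting, balance scoring.

All three detectors consume unfiltered position data. Robustness against
sensor noise comes from hysteresis (two-threshold automata) and from time
integration over actual timestamp deltas, never from smoothing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .kinematics import (
    ANKLE_LEFT,
    ANKLE_RIGHT,
    KNEE_LEFT,
    KNEE_RIGHT,
    AngleSample,
    angle_series,
    com_series,
)
from .skeleton import JointName, SegmentTable, SkeletonStream

__all__ = [
    "FlexionConfig",
    "FlexionResult",
    "count_flexions",
    "StepConfig",
    "StepResult",
    "count_steps",
    "BalanceConfig",
    "BalanceResult",
    "score_balance",
    "BALANCE_DIRECTIONS",
    "DIRECTION_UNIT_XZ",
]

_EPS = 1e-9


# --------------------------------------------------------------------------
# Flexion / extension counting
# --------------------------------------------------------------------------

@dataclass
class FlexionConfig:
    """Hysteresis thresholds for one joint's flexion-extension counter.

    ``convention`` states the scale the thresholds live on. ``deviation``
    thresholds compare against the deviation angle directly (flexed when it
    rises to ``flexion_threshold_deg``, repetition completed when it falls
    back to ``extension_threshold_deg``); ``interior`` thresholds are
    interpreted on the anatomical angle 180 - deviation (flexed when the
    interior angle drops to the flexion threshold, completed when it opens
    back past the extension threshold). Input angle series are always
    deviation angles as produced by :func:`kinerehab.kinematics.angle_series`.

    Defaults follow clinical practice for hemophilic arthropathy patients:
    elbow (50, 100) interior; knee (70, 30) deviation.
    """

    joint: Literal["elbow", "knee"] = "knee"
    side: Literal["left", "right"] = "right"
    flexion_threshold_deg: float = 70.0
    extension_threshold_deg: float = 30.0
    convention: Literal["deviation", "interior"] = "deviation"

    def __post_init__(self) -> None:
        for v in (self.flexion_threshold_deg, self.extension_threshold_deg):
            if not 0.0 < v < 180.0:
                raise ValueError(f"threshold {v} out of (0, 180)")
        if self.flexion_threshold_deg == self.extension_threshold_deg:
            raise ValueError("flexion and extension thresholds must differ")

    @classmethod
    def elbow(cls, side: Literal["left", "right"] = "right") -> "FlexionConfig":
        return cls(joint="elbow", side=side, flexion_threshold_deg=50.0,
                   extension_threshold_deg=100.0, convention="interior")

    @classmethod
    def knee(cls, side: Literal["left", "right"] = "right") -> "FlexionConfig":
        return cls(joint="knee", side=side, flexion_threshold_deg=70.0,
                   extension_threshold_deg=30.0, convention="deviation")


@dataclass
class FlexionResult:
    """Counted repetitions with per-repetition event times and the full angle trace."""

    flex_count: int
    events: list[tuple[float, float]]  # (flexion-reached, extension-completed)
    angles: list[AngleSample]
    pending_flexion_at: float | None = None  # flexed state entered but not yet completed


def count_flexions(angles: Sequence[AngleSample], cfg: FlexionConfig) -> FlexionResult:
    """Count completed flexion-extension repetitions with a two-state hysteresis automaton.

    Starting in the *extended* state, the automaton switches to *flexed*
    when the angle crosses the flexed-side threshold, and counts one
    repetition (returning to *extended*) when the angle subsequently
    crosses the extended-side threshold. Values between the thresholds
    change nothing, which is what suppresses noise-induced double counts.
    Threshold comparisons are inclusive, so a trace pinned exactly on a
    threshold cannot oscillate the automaton.
    """
    samples = list(angles)
    if not samples:
        warnings.warn("empty angle series: flex_count is 0", stacklevel=2)
        return FlexionResult(0, [], [])

    interior = cfg.convention == "interior"
    flexed_state = False
    count = 0
    events: list[tuple[float, float]] = []
    t_flexed: float | None = None
    for s in samples:
        a = 180.0 - s.angle_deg if interior else s.angle_deg
        if interior:
            is_flex_cross = a <= cfg.flexion_threshold_deg
            is_ext_cross = a >= cfg.extension_threshold_deg
        else:
            is_flex_cross = a >= cfg.flexion_threshold_deg
            is_ext_cross = a <= cfg.extension_threshold_deg
        if not flexed_state and is_flex_cross:
            flexed_state = True
            t_flexed = s.timestamp
        elif flexed_state and is_ext_cross:
            flexed_state = False
            count += 1
            events.append((t_flexed, s.timestamp))  # type: ignore[arg-type]
            t_flexed = None
    return FlexionResult(count, events, samples,
                         pending_flexion_at=t_flexed if flexed_state else None)


# --------------------------------------------------------------------------
# Step-climb counting
# --------------------------------------------------------------------------

@dataclass
class StepConfig:
    """Parameters of the step-climb detector.

    A climb requires both (a) a general rise of the body, measured at the
    hip center (SpineBase) against a standing baseline, and (b) a
    flexion-extension cycle of the leading knee overlapping the rise in
    time. ``hip_rise_threshold_m`` defaults to 0.09 m, roughly 60% of the
    nominal 0.15 m step height (which is carried as metadata only). The
    ankle angle history is recorded for clinical review but never consulted
    for detection.
    """

    hip_rise_threshold_m: float = 0.09
    step_height_m: float = 0.15  # metadata, not a detection input
    knee_flexion_threshold_deg: float = 70.0
    knee_extension_threshold_deg: float = 30.0
    baseline_window_s: float = 2.0

    def __post_init__(self) -> None:
        if not self.hip_rise_threshold_m > 0:
            raise ValueError("hip rise threshold must be positive")
        if not self.baseline_window_s > 0:
            raise ValueError("baseline window must be positive")

    def knee_config(self, side: Literal["left", "right"]) -> FlexionConfig:
        return FlexionConfig(
            joint="knee", side=side,
            flexion_threshold_deg=self.knee_flexion_threshold_deg,
            extension_threshold_deg=self.knee_extension_threshold_deg,
            convention="deviation",
        )


@dataclass
class StepResult:
    """Climb/descent counts per foot and the recorded (unused) ankle angle history."""

    climbs: dict[str, int]
    descents: dict[str, int]
    ankle_angles: dict[str, list[AngleSample]]
    knee_results: dict[str, FlexionResult] = field(default_factory=dict)
    hip_baseline_m: float = float("nan")


def _hip_rise_episodes(
    hip: list[tuple[float, float]], cfg: StepConfig
) -> list[tuple[float, float]]:
    """Intervals where the hip center is raised above baseline by the threshold.

    Baseline starts as the mean over the initial calibration window and is
    re-anchored over a fresh window after each completed descent, so slow
    postural drift does not accumulate. An episode closes when the hip
    returns within half the rise threshold of baseline.
    """
    t0 = hip[0][0]
    calib = [y for t, y in hip if t <= t0 + cfg.baseline_window_s + _EPS]
    baseline = float(np.mean(calib))
    episodes: list[tuple[float, float]] = []
    raised = False
    t_up = 0.0
    reanchor_until: float | None = None
    reanchor_vals: list[float] = []
    for t, y in hip:
        if t <= t0 + cfg.baseline_window_s + _EPS:
            continue
        if reanchor_until is not None:
            reanchor_vals.append(y)
            if t >= reanchor_until - _EPS:
                baseline = float(np.mean(reanchor_vals))
                reanchor_until = None
                reanchor_vals = []
        rise = y - baseline
        if not raised and rise >= cfg.hip_rise_threshold_m - _EPS:
            raised = True
            t_up = t
        elif raised and rise <= cfg.hip_rise_threshold_m / 2.0 + _EPS:
            raised = False
            episodes.append((t_up, t))
            reanchor_until = t + cfg.baseline_window_s
            reanchor_vals = []
    if raised:
        episodes.append((t_up, math.inf))  # climb without completed descent
    return episodes


def count_steps(stream: SkeletonStream, cfg: StepConfig | None = None) -> StepResult:
    """Count step climbs and descents per foot.

    A climb on foot F is registered when a hip-rise episode and a knee-F
    flexion-extension cycle overlap in time; the matching descent is
    registered when the hip returns to baseline afterwards. Frames with
    NotTracked joints are skipped; only a stream with no usable hip-center
    samples at all is an error.
    """
    cfg = cfg or StepConfig()
    hip: list[tuple[float, float]] = []
    for frame in stream:
        if frame.has(JointName.SpineBase):
            hip.append((frame.timestamp, float(frame.position(JointName.SpineBase)[1])))
    if not hip:
        raise ValueError("no frames with a tracked hip center (SpineBase); cannot detect steps")

    knee_results = {
        "left": count_flexions(angle_series(stream, KNEE_LEFT), cfg.knee_config("left")),
        "right": count_flexions(angle_series(stream, KNEE_RIGHT), cfg.knee_config("right")),
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # ankle history is best-effort pass-through
        ankle_angles = {
            "left": angle_series(stream, ANKLE_LEFT),
            "right": angle_series(stream, ANKLE_RIGHT),
        }

    episodes = _hip_rise_episodes(hip, cfg)
    climbs = {"left": 0, "right": 0}
    descents = {"left": 0, "right": 0}
    consumed: dict[str, set[int]] = {"left": set(), "right": set()}
    for t_up, t_down in episodes:
        for side in ("left", "right"):
            for i, (t_flex, t_ext) in enumerate(knee_results[side].events):
                if i in consumed[side]:
                    continue
                if t_flex <= t_down + _EPS and t_ext >= t_up - _EPS:
                    consumed[side].add(i)
                    climbs[side] += 1
                    if math.isfinite(t_down):
                        descents[side] += 1
                    break

    t0 = hip[0][0]
    base = float(np.mean([y for t, y in hip if t <= t0 + cfg.baseline_window_s + _EPS]))
    return StepResult(climbs, descents, ankle_angles, knee_results, base)


# --------------------------------------------------------------------------
# Multi-directional balance scoring
# --------------------------------------------------------------------------

BALANCE_DIRECTIONS = ("N", "NE", "E", "SE", "S", "SW", "W", "NW")

_SQ2 = math.sqrt(0.5)
# Unit vectors in the (x, z) floor plane. N is the subject's front-facing
# direction, i.e. toward the sensor (-z in camera space); E is +x.
DIRECTION_UNIT_XZ: dict[str, tuple[float, float]] = {
    "N": (0.0, -1.0),
    "NE": (_SQ2, -_SQ2),
    "E": (1.0, 0.0),
    "SE": (_SQ2, _SQ2),
    "S": (0.0, 1.0),
    "SW": (-_SQ2, _SQ2),
    "W": (-1.0, 0.0),
    "NW": (-_SQ2, -_SQ2),
}

_LEVEL_EXCURSION_M = {1: 0.04, 2: 0.06, 3: 0.08}


@dataclass
class BalanceConfig:
    """Geometry and timing of the 8-direction balance protocol.

    Directions are visited in fixed clockwise order N, NE, E, SE, S, SW, W,
    NW. Each target center sits at ``excursion_m`` from the calibrated idle
    position along the direction's unit vector in the XZ plane; the subject
    scores the fraction of the 10 s window spent within ``target_radius_m``
    of the center, and must return within ``idle_radius_m`` of the idle
    position before the next window opens. Difficulty levels 1-3 increase
    the excursion (4/6/8 cm by default).
    """

    level: Literal[1, 2, 3] = 1
    excursions_m: tuple[float, float, float] = (0.04, 0.06, 0.08)
    target_radius_m: float = 0.015
    time_per_target_s: float = 10.0
    idle_radius_m: float = 0.015
    calibration_window_s: float = 2.0

    def __post_init__(self) -> None:
        if self.level not in (1, 2, 3):
            raise ValueError("level must be 1, 2 or 3")
        e1, e2, e3 = self.excursions_m
        if not (0 < e1 < e2 < e3):
            raise ValueError("excursions must be positive and strictly increasing")
        for v in (self.target_radius_m, self.idle_radius_m, self.time_per_target_s,
                  self.calibration_window_s):
            if not v > 0:
                raise ValueError("radii and durations must be positive")

    @property
    def excursion_m(self) -> float:
        return self.excursions_m[self.level - 1]


@dataclass
class BalanceResult:
    """Per-direction percentage-of-time-on-target scores for one protocol run."""

    scores: np.ndarray  # shape (8,), percent in [0, 100], N..NW order
    on_target_s: np.ndarray  # shape (8,), seconds
    idle_pos: np.ndarray  # shape (3,), mean COM over the calibration window
    completed: np.ndarray  # shape (8,), bool: whether the window fully elapsed
    directions: tuple[str, ...] = BALANCE_DIRECTIONS


def score_balance(
    stream: SkeletonStream,
    cfg: BalanceConfig | None = None,
    table: SegmentTable | None = None,
    mass_kg: float | None = None,
) -> BalanceResult:
    """Score an 8-direction balance session from the whole-body COM trajectory.

    The idle position is the mean COM over the initial calibration window.
    Each direction's scoring window opens at the first frame (after the
    previous window closed) where the COM lies within the idle radius of
    the idle position, lasts ``time_per_target_s``, and accumulates
    per-frame timestamp deltas while the COM is within the target radius of
    that direction's target center. The score is 100 x on-target time /
    allowed time. Directions whose window never fully elapsed before the
    stream ended are flagged incomplete.
    """
    from .skeleton import default_segment_table  # local import to avoid cycle at module load

    cfg = cfg or BalanceConfig()
    table = table or default_segment_table()
    mass = mass_kg if mass_kg is not None else stream.subject.mass_kg

    coms = com_series(stream, table, mass)
    if not coms:
        raise ValueError("no frames usable for COM computation")

    t0 = coms[0].timestamp
    calib = np.array([c.com for c in coms if c.timestamp <= t0 + cfg.calibration_window_s + _EPS])
    idle_pos = calib.mean(axis=0)
    idle_xz = np.array([idle_pos[0], idle_pos[2]])

    targets = {
        d: idle_xz + cfg.excursion_m * np.array(DIRECTION_UNIT_XZ[d])
        for d in BALANCE_DIRECTIONS
    }

    on_target = np.zeros(8)
    completed = np.zeros(8, dtype=bool)
    d = 0
    in_window = False
    t_end = 0.0
    prev_t: float | None = None
    for c in coms:
        if c.timestamp <= t0 + cfg.calibration_window_s + _EPS:
            prev_t = c.timestamp
            continue
        xz = np.array([c.com[0], c.com[2]])
        if in_window and c.timestamp > t_end + _EPS:
            completed[d] = True
            d += 1
            in_window = False
        if d >= 8:
            break
        if not in_window:
            if np.linalg.norm(xz - idle_xz) <= cfg.idle_radius_m + _EPS:
                in_window = True
                t_end = c.timestamp + cfg.time_per_target_s
        else:
            dt = c.timestamp - prev_t if prev_t is not None else 0.0
            if np.linalg.norm(xz - targets[BALANCE_DIRECTIONS[d]]) <= cfg.target_radius_m + _EPS:
                on_target[d] += dt
            if c.timestamp >= t_end - _EPS:
                completed[d] = True
                d += 1
                in_window = False
        prev_t = c.timestamp

    scores = np.clip(100.0 * on_target / cfg.time_per_target_s, 0.0, 100.0)
    if not completed.all():
        warnings.warn(
            f"balance stream ended after {int(completed.sum())} of 8 directions; "
            "remaining scores are from incomplete windows",
            stacklevel=2,
        )
    return BalanceResult(scores, on_target, idle_pos, completed)
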