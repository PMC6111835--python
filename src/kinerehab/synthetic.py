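"""Deterministic synthetic skeletal-motion generator.

Emulates the body-tracking output of a depth sensor at ~30 Hz for each
supported exercise: smooth analytic trajectories with configurable
repetition counts, amplitudes, cadence, additive position noise and
occasional NotTracked dropouts. Because the trajectories are synthesized
from a known plan, every session carries its own ground truth, which makes
the generator the oracle for the detector test suites. Trajectories are
kinematic stand-ins, not biomechanical simulations.

Sign conventions match camera space (y up, z from the sensor toward the
subject, subject facing the sensor); the floor sits at y = 0 and the
subject stands at z = 2.5 m.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .skeleton import (
    JointName,
    JointSample,
    SkeletonFrame,
    SkeletonStream,
    SubjectProfile,
    TrackingState,
)

__all__ = [
    "MotionPlan",
    "GroundTruth",
    "make_base_skeleton",
    "gen_flexion_session",
    "gen_step_session",
    "gen_balance_session",
    "generate_session",
]

_JOINTS = list(JointName)

# Neutral standing pose. Vertical coordinates are fractions of body height
# (feet on the floor); lateral/longitudinal offsets are absolute meters so
# that two subjects of different heights differ only by vertical scaling.
_POSE_Y_FRACTION: dict[JointName, float] = {
    JointName.SpineBase: 0.55,
    JointName.SpineMid: 0.70,
    JointName.SpineShoulder: 0.80,
    JointName.Neck: 0.86,
    JointName.Head: 0.93,
    JointName.ShoulderLeft: 0.82, JointName.ShoulderRight: 0.82,
    JointName.ElbowLeft: 0.62, JointName.ElbowRight: 0.62,
    JointName.WristLeft: 0.44, JointName.WristRight: 0.44,
    JointName.HandLeft: 0.41, JointName.HandRight: 0.41,
    JointName.HandTipLeft: 0.38, JointName.HandTipRight: 0.38,
    JointName.ThumbLeft: 0.42, JointName.ThumbRight: 0.42,
    JointName.HipLeft: 0.53, JointName.HipRight: 0.53,
    JointName.KneeLeft: 0.29, JointName.KneeRight: 0.29,
    JointName.AnkleLeft: 0.04, JointName.AnkleRight: 0.04,
    JointName.FootLeft: 0.0, JointName.FootRight: 0.0,
}

_ARM_X = 0.20
_LEG_X = 0.10
_POSE_X_M: dict[JointName, float] = {
    **{j: 0.0 for j in (JointName.SpineBase, JointName.SpineMid, JointName.SpineShoulder,
                        JointName.Neck, JointName.Head)},
    **{JointName(f"{name}{side}"): sign * x
       for name, x in (("Shoulder", _ARM_X), ("Elbow", _ARM_X), ("Wrist", _ARM_X),
                       ("Hand", _ARM_X), ("HandTip", _ARM_X), ("Thumb", _ARM_X - 0.02),
                       ("Hip", _LEG_X), ("Knee", _LEG_X), ("Ankle", _LEG_X),
                       ("Foot", _LEG_X))
       for side, sign in (("Left", -1.0), ("Right", 1.0))},
}

_SUBJECT_Z = 2.5
_POSE_Z_M: dict[JointName, float] = {j: _SUBJECT_Z for j in _JOINTS}
_POSE_Z_M[JointName.FootLeft] = _SUBJECT_Z - 0.10  # toes point toward the sensor
_POSE_Z_M[JointName.FootRight] = _SUBJECT_Z - 0.10
_POSE_Z_M[JointName.ThumbLeft] = _SUBJECT_Z - 0.02
_POSE_Z_M[JointName.ThumbRight] = _SUBJECT_Z - 0.02

# Default deviation-angle amplitudes that carry the joint through its
# detector's hysteresis band: knee band 70/30 (deviation), elbow band
# 50/100 on the interior angle, i.e. 130/80 in deviation terms.
_DEFAULT_AMPLITUDE_DEG = {"squat": 90.0, "elbow": 150.0}
_FLEX_REACH_DEG = {"squat": 70.0, "elbow": 130.0}


@dataclass
class MotionPlan:
    """Recipe for one synthetic exercise session.

    ``compliance`` (balance only) gives, per direction N..NW, the fraction
    of the 10 s scoring window spent on target. ``amplitude_deg`` is the
    peak deviation angle of the flexing joint; ``None`` selects the
    exercise default. ``dropout_joints`` restricts which joints may be
    flagged NotTracked (``None`` = all).
    """

    exercise: Literal["elbow", "squat", "step", "balance"] = "squat"
    repetitions: int = 5
    side: Literal["left", "right", "alternate"] = "right"
    compliance: tuple[float, ...] = (1.0,) * 8
    amplitude_deg: float | None = None
    cadence_rpm: float = 15.0
    step_rise_m: float = 0.15
    noise_sigma_m: float = 0.0
    angle_noise_deg: float = 0.0
    dropout_rate: float = 0.0
    dropout_joints: tuple[JointName, ...] | None = None
    seed: int = 0
    sample_rate_hz: float = 30.0
    height_m: float = 1.72
    mass_kg: float = 70.0

    def __post_init__(self) -> None:
        if self.repetitions < 0:
            raise ValueError("repetitions must be non-negative")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        if self.exercise == "balance":
            if len(self.compliance) != 8:
                raise ValueError("balance compliance plan needs 8 fractions")
            if any(not 0.0 <= f <= 1.0 for f in self.compliance):
                raise ValueError("compliance fractions must be in [0, 1]")
        if not self.cadence_rpm > 0:
            raise ValueError("cadence must be positive")


@dataclass
class GroundTruth:
    """What was planted in a synthetic session, for detector verification."""

    exercise: str
    flex_counts: dict[str, int] = field(default_factory=dict)  # side -> reps
    step_climbs: dict[str, int] = field(default_factory=dict)  # foot -> climbs
    step_descents: dict[str, int] = field(default_factory=dict)
    balance_on_target_s: tuple[float, ...] = ()
    balance_scores_pct: tuple[float, ...] = ()
    amplitude_reachable: bool = True


def make_base_skeleton(height_m: float = 1.72, timestamp: float = 0.0,
                       body_id: int = 0) -> SkeletonFrame:
    """Neutral standing pose facing the sensor, feet on the floor at z = 2.5 m."""
    if not height_m > 0:
        raise ValueError("height must be positive")
    joints = {
        j: JointSample(
            np.array([_POSE_X_M[j], _POSE_Y_FRACTION[j] * height_m, _POSE_Z_M[j]]),
            TrackingState.Tracked,
        )
        for j in _JOINTS
    }
    return SkeletonFrame(timestamp, body_id, joints)


def _base_positions(height_m: float) -> np.ndarray:
    """Pose as a (25, 3) array in JointName declaration order."""
    frame = make_base_skeleton(height_m)
    return np.stack([frame.joints[j].position for j in _JOINTS])


def _rotate_about_x(points: np.ndarray, pivot: np.ndarray, theta_rad: float) -> np.ndarray:
    """Rotate points about the x axis through ``pivot`` (sagittal-plane motion)."""
    r = points - pivot
    c, s = np.cos(theta_rad), np.sin(theta_rad)
    out = r.copy()
    out[..., 1] = c * r[..., 1] - s * r[..., 2]
    out[..., 2] = s * r[..., 1] + c * r[..., 2]
    return out + pivot


def _bump(t: np.ndarray, t_start: float, duration: float) -> np.ndarray:
    """Raised-cosine bump: 0 at the edges, 1 at the midpoint, 0 outside."""
    u = (t - t_start) / duration
    out = np.zeros_like(t)
    mask = (u >= 0.0) & (u <= 1.0)
    out[mask] = 0.5 * (1.0 - np.cos(2.0 * np.pi * u[mask]))
    return out


def _ramp(t: np.ndarray, t_start: float, duration: float) -> np.ndarray:
    """Half-cosine ramp: 0 before t_start, 1 after t_start + duration."""
    u = np.clip((t - t_start) / duration, 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * u))


def _assemble_stream(positions: np.ndarray, plan: MotionPlan,
                     rng: np.random.Generator) -> SkeletonStream:
    """Apply position noise and dropouts, then box frames into a stream."""
    n = positions.shape[0]
    if plan.noise_sigma_m > 0.0:
        positions = positions + rng.normal(0.0, plan.noise_sigma_m, positions.shape)
    dropped = np.zeros((n, len(_JOINTS)), dtype=bool)
    if plan.dropout_rate > 0.0:
        eligible = np.ones(len(_JOINTS), dtype=bool)
        if plan.dropout_joints is not None:
            eligible = np.array([j in plan.dropout_joints for j in _JOINTS])
        dropped = (rng.random((n, len(_JOINTS))) < plan.dropout_rate) & eligible

    fs = plan.sample_rate_hz
    frames = []
    for i in range(n):
        joints = {
            j: JointSample(
                positions[i, k].copy(),
                TrackingState.NotTracked if dropped[i, k] else TrackingState.Tracked,
            )
            for k, j in enumerate(_JOINTS)
        }
        frames.append(SkeletonFrame(i / fs, 0, joints))
    subject = SubjectProfile("synthetic", plan.mass_kg, plan.height_m)
    return SkeletonStream(frames, fs, subject)


_FLEX_CHAINS = {
    ("elbow", "left"): (JointName.ElbowLeft,
                        (JointName.WristLeft, JointName.HandLeft,
                         JointName.HandTipLeft, JointName.ThumbLeft)),
    ("elbow", "right"): (JointName.ElbowRight,
                         (JointName.WristRight, JointName.HandRight,
                          JointName.HandTipRight, JointName.ThumbRight)),
    ("squat", "left"): (JointName.KneeLeft, (JointName.AnkleLeft, JointName.FootLeft)),
    ("squat", "right"): (JointName.KneeRight, (JointName.AnkleRight, JointName.FootRight)),
}


def _apply_flexion(positions: np.ndarray, exercise: str, side: str,
                   theta_deg: np.ndarray) -> None:
    """Rotate the distal chain about the apex joint, frame by frame, in place."""
    apex, distal = _FLEX_CHAINS[(exercise, side)]
    ai = _JOINTS.index(apex)
    di = [_JOINTS.index(j) for j in distal]
    for i in np.nonzero(theta_deg != 0.0)[0]:
        pivot = positions[i, ai]
        positions[i, di] = _rotate_about_x(positions[i, di], pivot,
                                           np.radians(theta_deg[i]))


def gen_flexion_session(plan: MotionPlan) -> tuple[SkeletonStream, GroundTruth]:
    """Synthesize an elbow-flexion or squat session.

    The deviation angle of the chosen joint follows a raised-cosine bump
    per repetition at the planned cadence, realized by rotating the distal
    segment chain about the apex joint; the rest of the body stands still.
    Angle noise perturbs the rotation geometrically so detectors only ever
    see positions. If the amplitude cannot reach the exercise's default
    flexion threshold the session is still generated but the ground truth
    records zero reachable repetitions.
    """
    if plan.exercise not in ("elbow", "squat"):
        raise ValueError(f"not a flexion exercise: {plan.exercise}")
    if plan.side == "alternate":
        raise ValueError("flexion sessions use a single side")
    rng = np.random.default_rng(plan.seed)
    fs = plan.sample_rate_hz
    amp = plan.amplitude_deg if plan.amplitude_deg is not None \
        else _DEFAULT_AMPLITUDE_DEG[plan.exercise]
    rep_period = 60.0 / plan.cadence_rpm
    lead, tail = 1.0, 1.0
    duration = lead + plan.repetitions * rep_period + tail
    n = int(round(duration * fs)) + 1
    t = np.arange(n) / fs

    theta = np.zeros(n)
    for r in range(plan.repetitions):
        theta += amp * _bump(t, lead + r * rep_period, rep_period)
    if plan.angle_noise_deg > 0.0:
        theta = theta + rng.normal(0.0, plan.angle_noise_deg, n)

    positions = np.broadcast_to(_base_positions(plan.height_m), (n, 25, 3)).copy()
    _apply_flexion(positions, plan.exercise, plan.side, theta)
    stream = _assemble_stream(positions, plan, rng)

    reachable = amp >= _FLEX_REACH_DEG[plan.exercise]
    truth = GroundTruth(
        exercise=plan.exercise,
        flex_counts={plan.side: plan.repetitions if reachable else 0},
        amplitude_reachable=reachable,
    )
    return stream, truth


# Timing of one climb block (seconds from block start): the knee cycle and
# the hip-rise plateau overlap by construction, as they do when a person
# leads a step climb with one leg.
_STEP_BLOCK_S = 6.5
_STEP_KNEE_START, _STEP_KNEE_DUR = 0.2, 2.8
_STEP_RISE_START, _STEP_RISE_DUR = 1.0, 1.0
_STEP_FALL_START, _STEP_FALL_DUR = 3.0, 1.0


def gen_step_session(plan: MotionPlan) -> tuple[SkeletonStream, GroundTruth]:
    """Synthesize a step-climb session.

    Each planted climb raises the whole body by ``step_rise_m`` along a
    half-cosine ramp while the leading knee performs one flexion-extension
    cycle overlapping the rise; the descent restores the standing baseline
    and leaves a standing gap long enough for the detector to re-anchor its
    baseline. A rise below the detector's hip threshold, or a knee
    amplitude below its band, yields a session whose ground truth plants
    zero climbs (tip-toe / knee-wiggle artifacts).
    """
    if plan.exercise != "step":
        raise ValueError(f"not a step exercise: {plan.exercise}")
    rng = np.random.default_rng(plan.seed)
    fs = plan.sample_rate_hz
    amp = plan.amplitude_deg if plan.amplitude_deg is not None else 90.0
    calib = 2.5
    duration = calib + plan.repetitions * _STEP_BLOCK_S + 0.5
    n = int(round(duration * fs)) + 1
    t = np.arange(n) / fs

    feet = []
    for r in range(plan.repetitions):
        if plan.side == "alternate":
            feet.append("right" if r % 2 == 0 else "left")
        else:
            feet.append(plan.side)

    rise = np.zeros(n)
    theta = {"left": np.zeros(n), "right": np.zeros(n)}
    for r, foot in enumerate(feet):
        b = calib + r * _STEP_BLOCK_S
        rise += plan.step_rise_m * (
            _ramp(t, b + _STEP_RISE_START, _STEP_RISE_DUR)
            - _ramp(t, b + _STEP_FALL_START, _STEP_FALL_DUR)
        )
        theta[foot] += amp * _bump(t, b + _STEP_KNEE_START, _STEP_KNEE_DUR)
    if plan.angle_noise_deg > 0.0:
        for side in ("left", "right"):
            theta[side] = theta[side] + rng.normal(0.0, plan.angle_noise_deg, n)

    positions = np.broadcast_to(_base_positions(plan.height_m), (n, 25, 3)).copy()
    positions[..., 1] += rise[:, None]
    for side in ("left", "right"):
        _apply_flexion(positions, "squat", side, theta[side])
    stream = _assemble_stream(positions, plan, rng)

    # Both detector conditions must be reachable for a climb to be real.
    cfg_reachable = plan.step_rise_m >= 0.09 and amp >= 70.0
    climbs = {"left": 0, "right": 0}
    for foot in feet:
        if cfg_reachable:
            climbs[foot] += 1
    truth = GroundTruth(
        exercise="step",
        step_climbs=climbs,
        step_descents=dict(climbs),  # every planted climb descends
        amplitude_reachable=cfg_reachable,
    )
    return stream, truth


def gen_balance_session(plan: MotionPlan, excursion_m: float = 0.04,
                        time_per_target_s: float = 10.0,
                        calibration_window_s: float = 2.0) -> tuple[SkeletonStream, GroundTruth]:
    """Synthesize an 8-direction balance session.

    Whole-body lean is modeled as a rigid translation in the floor (XZ)
    plane, which moves the COM exactly with it. For each direction, the
    subject sits at the idle position when the scoring window opens, jumps
    onto the target center for the planned fraction of the window (a whole
    number of frames), and returns to idle for the remainder, so the
    planted on-target time is exact to one frame interval.
    """
    if plan.exercise != "balance":
        raise ValueError(f"not a balance exercise: {plan.exercise}")
    from .detectors import BALANCE_DIRECTIONS, DIRECTION_UNIT_XZ

    rng = np.random.default_rng(plan.seed)
    fs = plan.sample_rate_hz
    frames_per_window = int(round(time_per_target_s * fs))
    n_calib = int(round(calibration_window_s * fs)) + 1  # t = 0 .. window end inclusive
    n = n_calib + 8 * (frames_per_window + 1) + 1
    t = np.arange(n) / fs

    offsets = np.zeros((n, 2))  # (x, z) offset of the whole body from idle
    planted_s = []
    b = n_calib  # index of the frame at idle that opens the first window
    for d, name in enumerate(BALANCE_DIRECTIONS):
        n_on = int(round(plan.compliance[d] * frames_per_window))
        unit = np.array(DIRECTION_UNIT_XZ[name])
        offsets[b + 1: b + 1 + n_on] = excursion_m * unit
        planted_s.append(n_on / fs)
        b += frames_per_window + 1

    positions = np.broadcast_to(_base_positions(plan.height_m), (n, 25, 3)).copy()
    positions[..., 0] += offsets[:, 0:1]
    positions[..., 2] += offsets[:, 1:2]
    stream = _assemble_stream(positions, plan, rng)

    truth = GroundTruth(
        exercise="balance",
        balance_on_target_s=tuple(planted_s),
        balance_scores_pct=tuple(100.0 * s / time_per_target_s for s in planted_s),
    )
    return stream, truth


def generate_session(plan: MotionPlan, **kwargs) -> tuple[SkeletonStream, GroundTruth]:
    """Dispatch to the generator matching ``plan.exercise``."""
    if plan.exercise in ("elbow", "squat"):
        return gen_flexion_session(plan)
    if plan.exercise == "step":
        return gen_step_session(plan)
    return gen_balance_session(plan, **kwargs)
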