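"""Joint-angle and center-of-mass computation on validated skeleton frames.

Angles are reported as *deviation* angles between the direction vectors of
the two adjacent segments: 0 deg for a straight limb, growing with flexion.
The anatomical (interior) angle at a joint is its complement to 180 deg;
detectors that operate on interior thresholds perform that conversion
explicitly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .skeleton import (
    JointName,
    SegmentTable,
    SkeletonFrame,
    SkeletonStream,
    validate_frame,
)

__all__ = [
    "AngleSample",
    "JointTriple",
    "ComSample",
    "joint_angle",
    "angle_series",
    "segment_com",
    "body_com",
    "com_series",
    "com_displacement",
    "ELBOW_LEFT",
    "ELBOW_RIGHT",
    "KNEE_LEFT",
    "KNEE_RIGHT",
    "ANKLE_LEFT",
    "ANKLE_RIGHT",
]

logger = logging.getLogger(__name__)


class AngleSample(NamedTuple):
    """A joint angle at one instant: apex joint, time (s), deviation angle (deg)."""

    timestamp: float
    joint: JointName
    angle_deg: float


@dataclass(frozen=True)
class JointTriple:
    """Proximal-apex-distal joints defining the angle at the apex.

    The angle is measured between u = apex - proximal and
    v = distal - apex, i.e. between the directions of the two adjacent
    segments.
    """

    proximal: JointName
    apex: JointName
    distal: JointName

    def __post_init__(self) -> None:
        if len({self.proximal, self.apex, self.distal}) != 3:
            raise ValueError("joint triple must name three distinct joints")

    @property
    def joints(self) -> set[JointName]:
        return {self.proximal, self.apex, self.distal}


# Standard triples for the joints the exercises track.
ELBOW_LEFT = JointTriple(JointName.ShoulderLeft, JointName.ElbowLeft, JointName.WristLeft)
ELBOW_RIGHT = JointTriple(JointName.ShoulderRight, JointName.ElbowRight, JointName.WristRight)
KNEE_LEFT = JointTriple(JointName.HipLeft, JointName.KneeLeft, JointName.AnkleLeft)
KNEE_RIGHT = JointTriple(JointName.HipRight, JointName.KneeRight, JointName.AnkleRight)
ANKLE_LEFT = JointTriple(JointName.KneeLeft, JointName.AnkleLeft, JointName.FootLeft)
ANKLE_RIGHT = JointTriple(JointName.KneeRight, JointName.AnkleRight, JointName.FootRight)


class ComSample(NamedTuple):
    """Whole-body COM at one instant, with optional XZ displacement from a reference."""

    timestamp: float
    com: np.ndarray  # shape (3,)
    dx_m: float | None = None
    dz_m: float | None = None


def joint_angle(u: Sequence[float], v: Sequence[float]) -> float:
    """Angle in degrees between two 3-vectors, in [0, 180].

    Computed as atan2(|u x v|, u . v), which equals the plain arctangent of
    |u x v| / (u . v) on acute angles and extends it continuously through
    90 deg to obtuse configurations. Symmetric in its arguments and
    invariant to positive rescaling of either vector.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("joint_angle is undefined for zero-length vectors")
    cross = np.linalg.norm(np.cross(u, v))
    dot = float(np.dot(u, v))
    return float(np.degrees(np.arctan2(cross, dot)))


def angle_series(stream: SkeletonStream, triple: JointTriple) -> list[AngleSample]:
    """Deviation angle at the apex joint for every frame that passes validation.

    Frames rejected by the acquisition discard rule (missing or NotTracked
    joints) are skipped, never interpolated: downstream detectors rely on
    hysteresis, not smoothing, for robustness.
    """
    required = triple.joints
    out: list[AngleSample] = []
    for frame in stream:
        if not validate_frame(frame, required):
            continue
        u = frame.position(triple.apex) - frame.position(triple.proximal)
        v = frame.position(triple.distal) - frame.position(triple.apex)
        if np.linalg.norm(u) == 0.0 or np.linalg.norm(v) == 0.0:
            continue  # coincident joints: angle undefined, treat as invalid
        out.append(AngleSample(frame.timestamp, triple.apex, joint_angle(u, v)))
    if not out:
        warnings.warn(
            f"no frame passed validation for triple {triple.proximal.value}-"
            f"{triple.apex.value}-{triple.distal.value}; empty angle series",
            stacklevel=2,
        )
    return out


def segment_com(s1: Sequence[float], s2: Sequence[float]) -> np.ndarray:
    """COM of a segment with endpoint positions s1, s2: the midpoint s1 + (s2 - s1)/2."""
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    return s1 + (s2 - s1) / 2.0


def body_com(frame: SkeletonFrame, table: SegmentTable, mass_kg: float = 70.0) -> np.ndarray:
    """Whole-body COM as the mass-weighted mean of the 16 segment COMs.

    bCOM = sum_i M_i * sCOM_i / sum_i M_i with M_i = fraction_i * M. The
    normalization uses the realized fraction total (99.98% for the default
    table) rather than M itself, so the result depends only on the
    fractions, never on the absolute mass.
    """
    if not mass_kg > 0:
        raise ValueError("body mass must be positive")
    check = validate_frame(frame, table.endpoint_joints())
    if not check:
        raise ValueError(f"frame rejected for COM computation: {check.reason}")
    weighted = np.zeros(3)
    total = 0.0
    for seg in table:
        mid = segment_com(frame.position(seg.proximal), frame.position(seg.distal))
        weighted += seg.mass_fraction_pct * mid
        total += seg.mass_fraction_pct
    return weighted / total


def com_series(
    stream: SkeletonStream,
    table: SegmentTable,
    mass_kg: float = 70.0,
    reference: Sequence[float] | None = None,
) -> list[ComSample]:
    """Body COM per validated frame, optionally with XZ displacement from a reference."""
    required = table.endpoint_joints()
    out: list[ComSample] = []
    for frame in stream:
        if not validate_frame(frame, required):
            continue
        com = body_com(frame, table, mass_kg)
        if reference is not None:
            dx, dz = com_displacement(com, reference)
            out.append(ComSample(frame.timestamp, com, dx, dz))
        else:
            out.append(ComSample(frame.timestamp, com))
    if not out:
        logger.warning("no frame passed validation for COM computation")
    return out


def com_displacement(com: Sequence[float], reference: Sequence[float]) -> tuple[float, float]:
    """Transverse and longitudinal displacement (dx, dz) of the COM in the XZ plane.

    The vertical (y) component is ignored: balance targets live in the
    floor-parallel plane.
    """
    com = np.asarray(com, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if not np.all(np.isfinite(reference)):
        raise ValueError("reference point must be finite")
    return float(com[0] - reference[0]), float(com[2] - reference[2])
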