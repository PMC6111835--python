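"""Skeletal data model: joints, frames, streams, and the anthropometric segment table.

The coordinate convention follows Kinect V2 camera space: positions in
meters, ``x`` transverse, ``y`` vertical (up), ``z`` along the sensor-subject
axis (the sensor sits at the origin, nominally 1.2 m above the floor, with
the subject standing ~2.5 m away facing it). No unit conversion is applied
on input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, NamedTuple

import numpy as np

__all__ = [
    "JointName",
    "TrackingState",
    "JointSample",
    "SkeletonFrame",
    "SkeletonStream",
    "SubjectProfile",
    "Segment",
    "SegmentTable",
    "FrameValidation",
    "validate_frame",
    "default_segment_table",
]


class JointName(str, Enum):
    """The 25 joints of the Kinect V2 body model."""

    SpineBase = "SpineBase"
    SpineMid = "SpineMid"
    SpineShoulder = "SpineShoulder"
    Neck = "Neck"
    Head = "Head"
    ShoulderLeft = "ShoulderLeft"
    ShoulderRight = "ShoulderRight"
    ElbowLeft = "ElbowLeft"
    ElbowRight = "ElbowRight"
    WristLeft = "WristLeft"
    WristRight = "WristRight"
    HandLeft = "HandLeft"
    HandRight = "HandRight"
    HandTipLeft = "HandTipLeft"
    HandTipRight = "HandTipRight"
    ThumbLeft = "ThumbLeft"
    ThumbRight = "ThumbRight"
    HipLeft = "HipLeft"
    HipRight = "HipRight"
    KneeLeft = "KneeLeft"
    KneeRight = "KneeRight"
    AnkleLeft = "AnkleLeft"
    AnkleRight = "AnkleRight"
    FootLeft = "FootLeft"
    FootRight = "FootRight"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class TrackingState(str, Enum):
    """Per-joint tracking confidence reported by the sensor.

    Only ``NotTracked`` excludes a joint from analysis; ``Inferred``
    positions are accepted unchanged.
    """

    Tracked = "Tracked"
    Inferred = "Inferred"
    NotTracked = "NotTracked"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class JointSample(NamedTuple):
    """One joint observation: 3D position (m, camera space) and tracking state."""

    position: np.ndarray  # shape (3,), float64
    state: TrackingState = TrackingState.Tracked


@dataclass
class SkeletonFrame:
    """A timestamped snapshot of one body's joints."""

    timestamp: float
    body_id: int = 0
    joints: dict[JointName, JointSample] = field(default_factory=dict)

    def position(self, joint: JointName) -> np.ndarray:
        return self.joints[joint].position

    def has(self, joint: JointName) -> bool:
        s = self.joints.get(joint)
        return s is not None and s.state is not TrackingState.NotTracked


@dataclass
class SubjectProfile:
    """Subject metadata used by the mass model.

    ``mass_kg`` is the total body mass M distributed over segments by the
    anthropometric table; height is optional metadata.
    """

    id: str = "anonymous"
    mass_kg: float = 70.0
    height_m: float | None = None

    def __post_init__(self) -> None:
        if not self.mass_kg > 0:
            raise ValueError(f"subject mass must be positive, got {self.mass_kg}")
        if self.height_m is not None and not self.height_m > 0:
            raise ValueError(f"subject height must be positive, got {self.height_m}")


@dataclass
class SkeletonStream:
    """An ordered sequence of frames for a single body at a nominal rate."""

    frames: list[SkeletonFrame]
    sample_rate_hz: float = 30.0
    subject: SubjectProfile = field(default_factory=SubjectProfile)

    def __post_init__(self) -> None:
        if not self.sample_rate_hz > 0:
            raise ValueError("sample rate must be positive")
        ts = [f.timestamp for f in self.frames]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("frame timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[SkeletonFrame]:
        return iter(self.frames)

    @property
    def duration_s(self) -> float:
        if len(self.frames) < 2:
            return 0.0
        return self.frames[-1].timestamp - self.frames[0].timestamp


@dataclass(frozen=True)
class Segment:
    """One anthropometric body segment: endpoint joints and its mass fraction."""

    name: str
    proximal: JointName
    distal: JointName
    mass_fraction_pct: float


@dataclass(frozen=True)
class SegmentTable:
    """The 16-segment mass model used for whole-body COM estimation."""

    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        if len(self.segments) == 0:
            raise ValueError("segment table may not be empty")
        for s in self.segments:
            if not s.mass_fraction_pct > 0:
                raise ValueError(f"segment {s.name}: mass fraction must be positive")

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self) -> Iterator[Segment]:
        return iter(self.segments)

    @property
    def total_fraction_pct(self) -> float:
        return sum(s.mass_fraction_pct for s in self.segments)

    def endpoint_joints(self) -> set[JointName]:
        out: set[JointName] = set()
        for s in self.segments:
            out.add(s.proximal)
            out.add(s.distal)
        return out


@dataclass(frozen=True)
class FrameValidation:
    """Outcome of frame validation: accepted, or rejected with a reason."""

    accepted: bool
    reason: str | None = None

    def __bool__(self) -> bool:
        return self.accepted


def validate_frame(frame: SkeletonFrame, required: set[JointName]) -> FrameValidation:
    """Check a frame against the discard rule used during acquisition.

    A frame is rejected when it carries no joints at all (no body was
    detected) or when any required joint is missing or flagged
    ``NotTracked``. Accepted frames pass through unmodified -- there is no
    interpolation or filtering anywhere downstream; rejected frames are
    simply skipped.
    """
    unknown = {j for j in required if not isinstance(j, JointName)}
    if unknown:
        raise ValueError(f"required set contains non-joint entries: {unknown}")
    if not frame.joints:
        return FrameValidation(False, "no body")
    for joint in sorted(required, key=lambda j: j.value):
        sample = frame.joints.get(joint)
        if sample is None:
            return FrameValidation(False, f"missing joint {joint.value}")
        if sample.state is TrackingState.NotTracked:
            return FrameValidation(False, f"NotTracked joint {joint.value}")
        if not np.all(np.isfinite(sample.position)):
            return FrameValidation(False, f"non-finite position for {joint.value}")
    return FrameValidation(True)


# Mass fractions (percent of total body mass, male anthropometric model).
# Bilateral segments are instantiated once per side with the same fraction;
# the ten distinct values sum to 99.98 over the 16 instances.
_AXIAL_FRACTIONS = {
    "Head": 8.26,
    "Thorax": 20.10,
    "Abdomen": 13.06,
    "Pelvis": 13.66,
}
_BILATERAL_FRACTIONS = {
    "Upper Arm": 3.25,
    "Forearm": 1.87,
    "Hand": 0.65,
    "Thigh": 10.50,
    "Leg": 4.75,
    "Foot": 1.43,
}

# Endpoint joints spanning each named anatomical segment with the nearest
# available joints of the 25-joint model. The pelvis spans the two hips.
_AXIAL_ENDPOINTS = {
    "Head": (JointName.Neck, JointName.Head),
    "Thorax": (JointName.Neck, JointName.SpineMid),
    "Abdomen": (JointName.SpineMid, JointName.SpineBase),
    "Pelvis": (JointName.HipLeft, JointName.HipRight),
}
_BILATERAL_ENDPOINTS = {
    "Upper Arm": ("Shoulder{side}", "Elbow{side}"),
    "Forearm": ("Elbow{side}", "Wrist{side}"),
    "Hand": ("Wrist{side}", "HandTip{side}"),
    "Thigh": ("Hip{side}", "Knee{side}"),
    "Leg": ("Knee{side}", "Ankle{side}"),
    "Foot": ("Ankle{side}", "Foot{side}"),
}


def default_segment_table() -> SegmentTable:
    """Build the default 16-segment mass model.

    Four axial segments plus six bilateral segments instantiated left and
    right. Fractions total 99.98% of body mass; COM computation normalizes
    by the realized total so the 0.02% deficit has no effect.
    """
    segments: list[Segment] = []
    for name, frac in _AXIAL_FRACTIONS.items():
        prox, dist = _AXIAL_ENDPOINTS[name]
        segments.append(Segment(name, prox, dist, frac))
    for name, frac in _BILATERAL_FRACTIONS.items():
        prox_t, dist_t = _BILATERAL_ENDPOINTS[name]
        for side in ("Left", "Right"):
            segments.append(
                Segment(
                    f"{name} ({side.lower()})",
                    JointName(prox_t.format(side=side)),
                    JointName(dist_t.format(side=side)),
                    frac,
                )
            )
    table = SegmentTable(tuple(segments))
    assert len(table) == 16
    assert math.isclose(table.total_fraction_pct, 99.98, abs_tol=1e-9)
    return table
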