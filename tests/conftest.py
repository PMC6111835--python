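import numpy as np
import pytest

from kinerehab import (
    AngleSample,
    JointName,
    JointSample,
    SkeletonFrame,
    TrackingState,
    default_segment_table,
    make_base_skeleton,
)


@pytest.fixture(scope="session")
def segment_table():
    return default_segment_table()


@pytest.fixture
def base_frame():
    return make_base_skeleton(1.72)


def make_trace(values, dt=1.0 / 30.0, joint=JointName.KneeRight):
    """Build an angle-sample trace from plain deviation-angle values."""
    return [AngleSample(i * dt, joint, float(v)) for i, v in enumerate(values)]


def make_frame(positions, t=0.0, states=None):
    """Frame from a {JointName: (x, y, z)} mapping, Tracked unless overridden."""
    states = states or {}
    joints = {
        j: JointSample(np.asarray(p, dtype=float),
                       states.get(j, TrackingState.Tracked))
        for j, p in positions.items()
    }
    return SkeletonFrame(t, 0, joints)
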