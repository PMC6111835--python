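"""Joint angles, segment and body COM, and displacement computation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinerehab import (
    JointName,
    JointSample,
    Segment,
    SegmentTable,
    SkeletonFrame,
    SkeletonStream,
    TrackingState,
    angle_series,
    body_com,
    com_displacement,
    joint_angle,
    make_base_skeleton,
    segment_com,
)
from kinerehab.kinematics import KNEE_RIGHT

from conftest import make_frame

finite_coord = st.floats(-10, 10, allow_nan=False, allow_infinity=False)
nonzero_vec = st.tuples(finite_coord, finite_coord, finite_coord).filter(
    lambda v: np.linalg.norm(v) > 1e-6
)


class TestJointAngle:
    @pytest.mark.parametrize(
        "u,v,expected",
        [
            ((1, 0, 0), (0, 1, 0), 90.0),
            ((1, 0, 0), (2, 0, 0), 0.0),
            ((1, 0, 0), (-1, 0, 0), 180.0),
            ((1, 0, 0), (1, 1, 0), 45.0),
        ],
    )
    def test_closed_forms(self, u, v, expected):
        assert joint_angle(u, v) == pytest.approx(expected, abs=1e-12)

    def test_zero_vector_is_domain_error(self):
        with pytest.raises(ValueError):
            joint_angle((0, 0, 0), (1, 0, 0))

    @given(u=nonzero_vec, v=nonzero_vec)
    @settings(max_examples=200, deadline=None)
    def test_symmetric_and_in_range(self, u, v):
        a = joint_angle(u, v)
        assert 0.0 <= a <= 180.0
        assert a == pytest.approx(joint_angle(v, u), abs=1e-9)

    @given(u=nonzero_vec, v=nonzero_vec,
           a=st.floats(0.01, 100), b=st.floats(0.01, 100))
    @settings(max_examples=200, deadline=None)
    def test_invariant_to_positive_rescaling(self, u, v, a, b):
        scaled = joint_angle(np.array(u) * a, np.array(v) * b)
        assert scaled == pytest.approx(joint_angle(u, v), abs=1e-6)

    def test_obtuse_angle_is_continuous_through_90(self):
        # the two-argument arctangent extends the acute-angle formula
        assert joint_angle((1, 0, 0), (-1, 1e-9, 0)) == pytest.approx(180.0, abs=1e-4)
        assert joint_angle((1, 0, 0), (-1, 1, 0)) == pytest.approx(135.0, abs=1e-9)


class TestSegmentCom:
    @pytest.mark.parametrize(
        "s1,s2,expected",
        [
            ((0, 0, 0), (2, 0, 0), (1, 0, 0)),
            ((1, 2, 3), (1, 2, 3), (1, 2, 3)),
            ((0, 0, 0), (1, 2, 2), (0.5, 1, 1)),
        ],
    )
    def test_midpoint(self, s1, s2, expected):
        assert np.allclose(segment_com(s1, s2), expected, atol=1e-15)


class TestBodyCom:
    def test_all_joints_at_one_point(self, segment_table):
        p = np.array([0.3, 1.1, 2.2])
        frame = make_frame({j: p for j in JointName})
        assert np.allclose(body_com(frame, segment_table, 70.0), p, atol=1e-12)

    def test_translation_equivariance(self, base_frame, segment_table):
        t = np.array([0.17, -0.4, 1.23])
        shifted = make_frame(
            {j: s.position + t for j, s in base_frame.joints.items()}
        )
        a = body_com(base_frame, segment_table, 70.0)
        b = body_com(shifted, segment_table, 70.0)
        assert np.allclose(b - a, t, atol=1e-12)

    def test_matches_bruteforce_weighted_sum_oracle(self, base_frame, segment_table):
        # independent oracle: explicit enumeration of the 16 segments
        num = np.zeros(3)
        den = 0.0
        for seg in segment_table:
            p = base_frame.joints[seg.proximal].position
            q = base_frame.joints[seg.distal].position
            num = num + seg.mass_fraction_pct * 0.5 * (p + q)
            den += seg.mass_fraction_pct
        expected = num / den
        got = body_com(base_frame, segment_table, 70.0)
        assert np.allclose(got, expected, rtol=1e-12, atol=0)

    def test_independent_of_total_mass(self, base_frame, segment_table):
        assert np.allclose(
            body_com(base_frame, segment_table, 50.0),
            body_com(base_frame, segment_table, 120.0),
            atol=1e-15,
        )

    def test_single_segment_table_gives_its_midpoint(self, base_frame):
        table = SegmentTable(
            (Segment("Thigh only", JointName.HipRight, JointName.KneeRight, 100.0),)
        )
        expected = segment_com(
            base_frame.position(JointName.HipRight),
            base_frame.position(JointName.KneeRight),
        )
        assert np.allclose(body_com(base_frame, table, 70.0), expected, atol=1e-15)

    def test_inside_convex_hull_of_midpoints(self, base_frame, segment_table):
        mids = np.array([
            0.5 * (base_frame.joints[s.proximal].position
                   + base_frame.joints[s.distal].position)
            for s in segment_table
        ])
        com = body_com(base_frame, segment_table, 70.0)
        assert np.all(com >= mids.min(axis=0) - 1e-12)
        assert np.all(com <= mids.max(axis=0) + 1e-12)

    def test_nottracked_endpoint_rejects_frame(self, base_frame, segment_table):
        frame = make_frame(
            {j: s.position for j, s in base_frame.joints.items()},
            states={JointName.KneeLeft: TrackingState.NotTracked},
        )
        with pytest.raises(ValueError, match="rejected"):
            body_com(frame, segment_table, 70.0)


class TestAngleSeries:
    def _stream(self, frames):
        return SkeletonStream(frames)

    def test_collinear_joints_give_zero_deviation(self):
        frames = [
            make_frame(
                {
                    JointName.HipRight: (0.1, 1.0, 2.5),
                    JointName.KneeRight: (0.1, 0.5, 2.5),
                    JointName.AnkleRight: (0.1, 0.0, 2.5),
                },
                t=i / 30.0,
            )
            for i in range(10)
        ]
        series = angle_series(self._stream(frames), KNEE_RIGHT)
        assert len(series) == 10
        assert all(s.angle_deg == pytest.approx(0.0, abs=1e-9) for s in series)

    def test_apex_not_tracked_throughout_gives_empty_series_with_warning(self):
        frames = [
            make_frame(
                {
                    JointName.HipRight: (0.1, 1.0, 2.5),
                    JointName.KneeRight: (0.1, 0.5, 2.5),
                    JointName.AnkleRight: (0.1, 0.0, 2.4),
                },
                t=i / 30.0,
                states={JointName.KneeRight: TrackingState.NotTracked},
            )
            for i in range(5)
        ]
        with pytest.warns(UserWarning, match="no frame passed validation"):
            series = angle_series(self._stream(frames), KNEE_RIGHT)
        assert series == []

    def test_length_equals_validated_frame_count(self):
        frames = []
        for i in range(20):
            states = (
                {JointName.AnkleRight: TrackingState.NotTracked} if i % 4 == 0 else {}
            )
            frames.append(
                make_frame(
                    {
                        JointName.HipRight: (0.1, 1.0, 2.5),
                        JointName.KneeRight: (0.1, 0.5, 2.5),
                        JointName.AnkleRight: (0.1, 0.0, 2.4),
                    },
                    t=i / 30.0,
                    states=states,
                )
            )
        series = angle_series(self._stream(frames), KNEE_RIGHT)
        assert len(series) == sum(1 for i in range(20) if i % 4 != 0)


class TestComDisplacement:
    def test_identity(self):
        ref = np.array([0.1, 1.0, 2.5])
        assert com_displacement(ref, ref) == (0.0, 0.0)

    def test_vertical_motion_invisible_in_xz(self):
        ref = np.array([0.0, 1.0, 2.5])
        dx, dz = com_displacement(ref + np.array([0.03, 0.50, 0.0]), ref)
        assert (dx, dz) == (pytest.approx(0.03), pytest.approx(0.0))

    def test_componentwise_subtraction(self):
        ref = np.array([0.0, 1.0, 2.5])
        dx, dz = com_displacement(ref + np.array([-0.02, 0.0, 0.04]), ref)
        assert (dx, dz) == (pytest.approx(-0.02), pytest.approx(0.04))

    def test_nonfinite_reference_is_error(self):
        with pytest.raises(ValueError):
            com_displacement(np.zeros(3), np.array([np.nan, 0, 0]))
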