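"""Stream formats, achievement aggregation, and report generation."""

import json

import numpy as np
import pytest

from kinerehab import (
    MotionPlan,
    SessionRecord,
    StreamParseError,
    achievement_rate,
    aggregate_achievement,
    count_flexions,
    angle_series,
    gen_flexion_session,
    make_report,
    read_stream,
    read_streams,
    write_stream,
    FlexionConfig,
    JointName,
    SubjectProfile,
)
from kinerehab.kinematics import KNEE_RIGHT
from kinerehab.skeleton import JointSample, SkeletonFrame, SkeletonStream


@pytest.fixture(scope="module")
def squat_stream():
    stream, _ = gen_flexion_session(
        MotionPlan(exercise="squat", repetitions=2, seed=9, noise_sigma_m=0.001))
    return stream


class TestRoundTrip:
    @pytest.mark.parametrize("suffix", [".csv", ".json"])
    def test_write_then_read_is_lossless(self, squat_stream, tmp_path, suffix):
        path = tmp_path / f"stream{suffix}"
        write_stream(squat_stream, path)
        back = read_stream(path)
        assert len(back) == len(squat_stream)
        for fa, fb in zip(squat_stream, back):
            assert fb.timestamp == fa.timestamp
            assert fb.joints.keys() == fa.joints.keys()
            for j in fa.joints:
                # bit-identical positions through the canonical dialect
                assert np.array_equal(fb.joints[j].position, fa.joints[j].position)
                assert fb.joints[j].state == fa.joints[j].state

    def test_json_envelope_preserves_subject(self, tmp_path):
        stream, _ = gen_flexion_session(MotionPlan(exercise="squat", repetitions=1, seed=0))
        path = tmp_path / "session.json"
        write_stream(stream, path, exercise="squat")
        back = read_stream(path)
        assert back.subject.mass_kg == stream.subject.mass_kg
        assert back.subject.height_m == stream.subject.height_m


class TestParseErrors:
    def test_unknown_joint_name_reports_line(self, squat_stream, tmp_path):
        path = tmp_path / "bad.csv"
        write_stream(squat_stream, path)
        text = path.read_text().replace("KneeRight", "Kneee", 1)
        path.write_text(text)
        with pytest.raises(StreamParseError) as err:
            read_stream(path)
        assert any("Kneee" in e and "line" in e for e in err.value.errors)

    def test_wrong_header_is_rejected(self, tmp_path):
        path = tmp_path / "hdr.csv"
        path.write_text("a,b,c\n1,2,3\n")
        with pytest.raises(StreamParseError, match="header"):
            read_stream(path)

    def test_malformed_number_reports_line(self, tmp_path):
        path = tmp_path / "num.csv"
        path.write_text(
            "time_s,body_id,joint,x_m,y_m,z_m,state\n"
            "0.0,0,Head,0.0,oops,2.5,Tracked\n"
        )
        with pytest.raises(StreamParseError, match="line 2"):
            read_stream(path)

    def test_non_monotone_timestamps_rejected(self, tmp_path):
        path = tmp_path / "mono.csv"
        path.write_text(
            "time_s,body_id,joint,x_m,y_m,z_m,state\n"
            "0.5,0,Head,0.0,1.7,2.5,Tracked\n"
            "0.1,0,Head,0.0,1.7,2.5,Tracked\n"
        )
        with pytest.raises(StreamParseError, match="non-monotone"):
            read_stream(path)


class TestMultiBody:
    def test_two_body_ids_become_two_streams(self, tmp_path):
        frames = []
        for body in (0, 1):
            for i in range(3):
                frames.append(SkeletonFrame(
                    i / 30.0, body,
                    {JointName.SpineBase:
                     JointSample(np.array([0.0, 1.0, 2.5 + body]))},
                ))
        path = tmp_path / "two.csv"
        # write interleaved rows by hand through the single-stream writer twice
        write_stream(SkeletonStream([f for f in frames if f.body_id == 0]), path)
        text = path.read_text()
        extra = "\n".join(
            f"{repr(f.timestamp)},1,SpineBase,0.0,1.0,{repr(2.5 + 1.0)},Tracked"
            for f in frames if f.body_id == 1
        )
        path.write_text(text + extra + "\n")
        streams = read_streams(path)
        assert len(streams) == 2
        assert streams[0].frames[0].body_id == 0
        assert streams[1].frames[0].body_id == 1
        with pytest.raises(ValueError, match="2 bodies"):
            read_stream(path)
        assert read_stream(path, body_id=1).frames[0].body_id == 1


class TestAchievement:
    def test_controls_right_step_mean(self):
        rates = (80, 88, 84, 76, 80, 72, 72, 80, 68, 80)
        summary = aggregate_achievement(rates)
        assert summary.mean_display == 78

    def test_patients_right_knee_mean(self):
        rates = (100, 92, 100, 72, 100, 60, 64, 100)
        summary = aggregate_achievement(rates)
        assert summary.mean_display == 86

    def test_patients_right_step_mean(self):
        rates = (64, 52, 80, 68, 64, 52, 68, 80)
        summary = aggregate_achievement(rates)
        assert summary.mean_display == 66

    def test_constant_series_has_zero_sd(self):
        summary = aggregate_achievement((100, 100, 100))
        assert summary.mean_display == 100
        assert summary.sd_pct == 0.0

    def test_mean_within_rate_range_and_sample_sd(self):
        rates = (60, 70, 95)
        summary = aggregate_achievement(rates)
        assert min(rates) <= summary.mean_pct <= max(rates)
        assert summary.sd_pct == pytest.approx(np.std(rates, ddof=1))

    def test_empty_sequence_is_an_error(self):
        with pytest.raises(ValueError):
            aggregate_achievement(())

    def test_rate_is_capped_at_100(self):
        assert achievement_rate(7, 5) == 100.0
        assert achievement_rate(4, 5) == 80.0
        assert achievement_rate(0, 5) == 0.0

    def test_display_rounding_half_away_from_zero(self):
        assert aggregate_achievement((75, 76)).mean_display == 76  # 75.5 rounds up


class TestReports:
    def _record(self, squat_stream):
        result = count_flexions(angle_series(squat_stream, KNEE_RIGHT),
                                FlexionConfig.knee("right"))
        return SessionRecord(
            SubjectProfile("subj-1", 70.0, 1.72), "squat",
            {"flexion_threshold_deg": 70.0, "extension_threshold_deg": 30.0},
            result, recorded_at="2026-01-15",
        )

    def test_report_contains_count_and_trace(self, squat_stream, tmp_path):
        record = self._record(squat_stream)
        files = make_report(record, tmp_path / "report", plots=False)
        doc = json.loads(files["json"].read_text())
        assert doc["result"]["flex_count"] == 2
        assert doc["exercise"] == "squat"
        assert files["angle"].exists()
        assert "Completed repetitions: 2" in files["summary"].read_text()

    def test_report_json_is_byte_stable(self, squat_stream, tmp_path):
        record = self._record(squat_stream)
        first = make_report(record, tmp_path / "a", plots=False)["json"].read_bytes()
        second = make_report(record, tmp_path / "b", plots=False)["json"].read_bytes()
        assert first == second

    def test_balance_report_lists_directions_in_order(self, tmp_path):
        from kinerehab import gen_balance_session, score_balance
        stream, _ = gen_balance_session(
            MotionPlan(exercise="balance", compliance=(1.0,) * 8, seed=0))
        record = SessionRecord(SubjectProfile(), "balance", {}, score_balance(stream))
        files = make_report(record, tmp_path / "bal", plots=False)
        doc = json.loads(files["json"].read_text())
        assert doc["result"]["directions"] == ["N", "NE", "E", "SE", "S", "SW", "W", "NW"]
        assert len(doc["result"]["scores_pct"]) == 8
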