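"""Canonical stream formats, achievement aggregation, and session reports.

Two interchangeable dialects are supported:

* ``canonical-csv`` — one row per joint per frame with header
  ``time_s,body_id,joint,x_m,y_m,z_m,state``. Floats are written with
  shortest round-trip repr, so write-then-read reproduces positions
  bit-identically.
* ``session-json`` — a JSON envelope that adds the subject profile and
  exercise metadata around the same per-frame records.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .detectors import BalanceResult, FlexionResult, StepResult
from .skeleton import (
    JointName,
    JointSample,
    SkeletonFrame,
    SkeletonStream,
    SubjectProfile,
    TrackingState,
)

__all__ = [
    "StreamParseError",
    "read_stream",
    "read_streams",
    "write_stream",
    "AchievementSummary",
    "achievement_rate",
    "aggregate_achievement",
    "SessionRecord",
    "make_report",
]

CSV_HEADER = ["time_s", "body_id", "joint", "x_m", "y_m", "z_m", "state"]


class StreamParseError(ValueError):
    """Raised when a stream file contains malformed records.

    ``errors`` lists one message per offending record, each carrying its
    line (CSV) or frame (JSON) number.
    """

    def __init__(self, errors: list[str]):
        self.errors = errors
        preview = "; ".join(errors[:5])
        more = f" (+{len(errors) - 5} more)" if len(errors) > 5 else ""
        super().__init__(f"{len(errors)} malformed record(s): {preview}{more}")


def _infer_dialect(path: Path) -> str:
    return "session-json" if path.suffix.lower() == ".json" else "canonical-csv"


def read_streams(path: str | Path, dialect: str | None = None) -> list[SkeletonStream]:
    """Read a stream file, returning one independent stream per body id.

    Multi-body recordings (the sensor tracks up to six bodies) are split so
    each body is analyzed on its own. Streams are ordered by body id.
    """
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "canonical-csv":
        return _read_csv(path)
    if dialect == "session-json":
        return _read_json(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def read_stream(path: str | Path, dialect: str | None = None,
                body_id: int | None = None) -> SkeletonStream:
    """Read a single-body stream; select ``body_id`` if several are present."""
    streams = read_streams(path, dialect)
    if body_id is not None:
        for s in streams:
            if s.frames and s.frames[0].body_id == body_id:
                return s
        raise ValueError(f"body id {body_id} not present in {path}")
    if len(streams) != 1:
        raise ValueError(
            f"{path} contains {len(streams)} bodies; pass body_id or use read_streams"
        )
    return streams[0]


def _rows_to_streams(rows: Iterable[tuple[int, float, int, JointName, np.ndarray, TrackingState]],
                     sample_rate: float, subject: SubjectProfile) -> list[SkeletonStream]:
    frames: dict[tuple[int, float], SkeletonFrame] = {}
    order: list[tuple[int, float]] = []
    for _line, t, body, joint, pos, state in rows:
        key = (body, t)
        if key not in frames:
            frames[key] = SkeletonFrame(t, body, {})
            order.append(key)
        frames[key].joints[joint] = JointSample(pos, state)

    by_body: dict[int, list[SkeletonFrame]] = {}
    for key in order:
        by_body.setdefault(key[0], []).append(frames[key])

    streams = []
    errors = []
    for body in sorted(by_body):
        fs = by_body[body]  # file order preserved: out-of-order records are errors
        ts = [f.timestamp for f in fs]
        for a, b in zip(ts, ts[1:]):
            if b <= a:
                errors.append(f"body {body}: non-monotone timestamps {a} -> {b}")
        if not errors:
            streams.append(SkeletonStream(fs, sample_rate, subject))
    if errors:
        raise StreamParseError(errors)
    return streams


def _parse_row(line_no: int, row: dict[str, str], errors: list[str]):
    try:
        joint = JointName(row["joint"])
    except ValueError:
        errors.append(f"line {line_no}: unknown joint name {row['joint']!r}")
        return None
    try:
        state = TrackingState(row["state"])
    except ValueError:
        errors.append(f"line {line_no}: unknown tracking state {row['state']!r}")
        return None
    try:
        t = float(row["time_s"])
        body = int(row["body_id"])
        pos = np.array([float(row["x_m"]), float(row["y_m"]), float(row["z_m"])])
    except (ValueError, TypeError):
        errors.append(f"line {line_no}: malformed numeric field")
        return None
    return line_no, t, body, joint, pos, state


def _read_csv(path: Path) -> list[SkeletonStream]:
    errors: list[str] = []
    rows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != CSV_HEADER:
            raise StreamParseError(
                [f"line 1: expected header {','.join(CSV_HEADER)}, got "
                 f"{','.join(reader.fieldnames or [])}"]
            )
        for line_no, row in enumerate(reader, start=2):
            parsed = _parse_row(line_no, row, errors)
            if parsed is not None:
                rows.append(parsed)
    if errors:
        raise StreamParseError(errors)
    return _rows_to_streams(rows, 30.0, SubjectProfile())


def write_stream(stream: SkeletonStream, path: str | Path,
                 dialect: str | None = None, exercise: str | None = None) -> None:
    """Write a stream in the canonical CSV or JSON session dialect."""
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "canonical-csv":
        _write_csv(stream, path)
    elif dialect == "session-json":
        _write_json(stream, path, exercise)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _write_csv(stream: SkeletonStream, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for frame in stream:
            for joint, sample in frame.joints.items():
                x, y, z = sample.position
                writer.writerow([repr(float(frame.timestamp)), frame.body_id,
                                 joint.value, repr(float(x)), repr(float(y)),
                                 repr(float(z)), sample.state.value])


def _write_json(stream: SkeletonStream, path: Path, exercise: str | None) -> None:
    doc = {
        "format": "kinerehab-session",
        "exercise": exercise,
        "subject": {
            "id": stream.subject.id,
            "mass_kg": stream.subject.mass_kg,
            "height_m": stream.subject.height_m,
        },
        "sample_rate_hz": stream.sample_rate_hz,
        "frames": [
            {
                "t": float(frame.timestamp),
                "body": frame.body_id,
                "joints": {
                    j.value: {"p": [float(v) for v in s.position], "s": s.state.value}
                    for j, s in frame.joints.items()
                },
            }
            for frame in stream
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def _read_json(path: Path) -> list[SkeletonStream]:
    with open(path) as fh:
        doc = json.load(fh)
    errors: list[str] = []
    rows = []
    sub = doc.get("subject") or {}
    subject = SubjectProfile(sub.get("id", "anonymous"), sub.get("mass_kg", 70.0),
                             sub.get("height_m"))
    for i, frame in enumerate(doc.get("frames", [])):
        t = frame.get("t")
        body = frame.get("body", 0)
        for jname, rec in frame.get("joints", {}).items():
            try:
                joint = JointName(jname)
            except ValueError:
                errors.append(f"frame {i}: unknown joint name {jname!r}")
                continue
            try:
                state = TrackingState(rec["s"])
                pos = np.array([float(v) for v in rec["p"]])
            except (ValueError, KeyError, TypeError):
                errors.append(f"frame {i}: malformed joint record for {jname}")
                continue
            rows.append((i, float(t), int(body), joint, pos, state))
    if errors:
        raise StreamParseError(errors)
    return _rows_to_streams(rows, doc.get("sample_rate_hz", 30.0), subject)


# --------------------------------------------------------------------------
# Achievement aggregation
# --------------------------------------------------------------------------

def _round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (display rule)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def achievement_rate(detected: int, prescribed: int = 5) -> float:
    """Percentage of prescribed repetitions detected in one series, capped at 100."""
    if prescribed <= 0:
        raise ValueError("prescribed repetitions must be positive")
    return min(100.0, 100.0 * detected / prescribed)


@dataclass(frozen=True)
class AchievementSummary:
    """Mean and sample standard deviation of per-series achievement rates."""

    rates_pct: tuple[float, ...]
    mean_pct: float
    sd_pct: float

    @property
    def mean_display(self) -> int:
        return _round_half_away(self.mean_pct)

    @property
    def sd_display(self) -> int:
        return _round_half_away(self.sd_pct)

    def __str__(self) -> str:
        return f"{self.mean_display} ± {self.sd_display}"


def aggregate_achievement(rates_pct: Sequence[float]) -> AchievementSummary:
    """Aggregate per-series achievement rates into mean +/- sample SD.

    Rates are percentages in [0, 100]; display values round half away from
    zero to whole percent, matching clinical reporting convention.
    """
    rates = tuple(float(r) for r in rates_pct)
    if not rates:
        raise ValueError("cannot aggregate an empty sequence of rates")
    for r in rates:
        if not 0.0 <= r <= 100.0:
            raise ValueError(f"rate {r} outside [0, 100]")
    mean = float(np.mean(rates))
    sd = float(np.std(rates, ddof=1)) if len(rates) > 1 else 0.0
    return AchievementSummary(rates, mean, sd)


# --------------------------------------------------------------------------
# Session reports
# --------------------------------------------------------------------------

@dataclass
class SessionRecord:
    """Everything needed to reproduce and report one analyzed session."""

    subject: SubjectProfile
    exercise: str
    config: dict
    result: FlexionResult | StepResult | BalanceResult | dict[str, FlexionResult]
    recorded_at: str = ""  # ISO date string supplied by the caller, not wall clock
    source: str = ""


def _result_payload(record: SessionRecord) -> dict:
    res = record.result
    if isinstance(res, dict):  # per-side flexion results
        return {
            "flex_counts": {side: r.flex_count for side, r in sorted(res.items())},
            "events": {side: r.events for side, r in sorted(res.items())},
        }
    if isinstance(res, FlexionResult):
        return {"flex_count": res.flex_count, "events": res.events}
    if isinstance(res, StepResult):
        return {
            "climbs": dict(sorted(res.climbs.items())),
            "descents": dict(sorted(res.descents.items())),
            "hip_baseline_m": res.hip_baseline_m,
        }
    if isinstance(res, BalanceResult):
        return {
            "directions": list(res.directions),
            "scores_pct": [float(s) for s in res.scores],
            "on_target_s": [float(s) for s in res.on_target_s],
            "idle_pos_m": [float(v) for v in res.idle_pos],
            "completed": [bool(c) for c in res.completed],
        }
    raise TypeError(f"unsupported result type {type(res).__name__}")


def _angle_traces(record: SessionRecord) -> dict[str, list]:
    res = record.result
    if isinstance(res, FlexionResult):
        return {"angle": res.angles}
    if isinstance(res, dict):
        return {f"angle_{side}": r.angles for side, r in sorted(res.items())}
    if isinstance(res, StepResult):
        out = {f"knee_{s}": r.angles for s, r in sorted(res.knee_results.items())}
        out.update({f"ankle_{s}": a for s, a in sorted(res.ankle_angles.items())})
        return out
    return {}


def make_report(record: SessionRecord, outdir: str | Path, plots: bool = True) -> dict[str, Path]:
    """Write a session report bundle: result JSON, text summary, CSV traces, plots.

    The JSON is fully determined by the record (sorted keys, no wall-clock
    stamps), so regenerating a report from the same record is
    byte-identical; plot images are exempt from that guarantee.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    payload = {
        "exercise": record.exercise,
        "subject": {
            "id": record.subject.id,
            "mass_kg": record.subject.mass_kg,
            "height_m": record.subject.height_m,
        },
        "recorded_at": record.recorded_at,
        "source": record.source,
        "config": record.config,
        "result": _result_payload(record),
    }
    json_path = outdir / "result.json"
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    files["json"] = json_path

    summary_path = outdir / "summary.txt"
    with open(summary_path, "w") as fh:
        fh.write(_summary_text(record, payload["result"]))
    files["summary"] = summary_path

    for name, trace in _angle_traces(record).items():
        trace_path = outdir / f"{name}.csv"
        with open(trace_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["time_s", "joint", "angle_deg"])
            for s in trace:
                writer.writerow([repr(float(s.timestamp)), s.joint.value,
                                 repr(float(s.angle_deg))])
        files[name] = trace_path

    if plots:
        files.update(_make_plots(record, outdir))
    return files


def _summary_text(record: SessionRecord, result: dict) -> str:
    lines = [
        f"Exercise session report: {record.exercise}",
        f"Subject: {record.subject.id} (mass {record.subject.mass_kg} kg)",
    ]
    if record.recorded_at:
        lines.append(f"Recorded: {record.recorded_at}")
    lines.append("")
    if "flex_count" in result:
        lines.append(f"Completed repetitions: {result['flex_count']}")
    if "flex_counts" in result:
        for side, c in result["flex_counts"].items():
            lines.append(f"Completed repetitions ({side}): {c}")
    if "climbs" in result:
        for side in ("left", "right"):
            lines.append(f"Step climbs ({side}): {result['climbs'][side]}, "
                         f"descents: {result['descents'][side]}")
    if "scores_pct" in result:
        lines.append("Balance scores (% time on target):")
        for d, s in zip(result["directions"], result["scores_pct"]):
            lines.append(f"  {d:>2}: {s:6.2f}")
    lines.append("")
    lines.append("Effective configuration:")
    for k, v in sorted(record.config.items()):
        lines.append(f"  {k} = {v}")
    return "\n".join(lines) + "\n"


def _make_plots(record: SessionRecord, outdir: Path) -> dict[str, Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    files: dict[str, Path] = {}
    traces = _angle_traces(record)
    if traces:
        fig, ax = plt.subplots(figsize=(8, 4))
        for name, trace in traces.items():
            if trace:
                ax.plot([s.timestamp for s in trace], [s.angle_deg for s in trace],
                        label=name, lw=1)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("deviation angle (deg)")
        ax.set_title(f"{record.exercise}: joint angle over time")
        ax.legend(loc="best", fontsize="small")
        fig.tight_layout()
        p = outdir / "angles.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        files["angles_plot"] = p

    res = record.result
    if isinstance(res, BalanceResult):
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.bar(range(8), res.scores, tick_label=list(res.directions))
        ax.set_ylim(0, 105)
        ax.set_ylabel("score (% time on target)")
        ax.set_title("balance scores by direction")
        fig.tight_layout()
        p = outdir / "balance_scores.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        files["balance_plot"] = p
    return files
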