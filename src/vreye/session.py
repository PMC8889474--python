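"""Session-log data model and on-disk I/O.

A participant's session log is the raw output of the VR paradigm: for each of
the six scenes, a regular 100 Hz timeseries (timestamp, raw gaze intersection
point, head pose, per-eye pupil diameter and eye openness, currently selected
object) plus event records logged at onset (gaze-object switches, blinks,
button presses, survey responses).

Missing pupil/openness readings — the tracker reports nothing while the
eyelid covers the pupil or on tracker dropout — are encoded on disk with the
sentinel ``-1.0`` (empty and ``null`` fields are also accepted on read) and
normalized internally to NaN (:data:`MISSING`).

On-disk layout, one directory per participant::

    <dir>/manifest.json              id, scene order, file map, baseline surveys
    <dir>/<scene>_samples.csv        t_ms,gx,gy,gz,hx,hy,hz,fx,fy,fz,
                                     pupil_l_mm,pupil_r_mm,open_l,open_r,object
    <dir>/<scene>_events.jsonl       {"t_ms": int, "kind": str, "payload": {...}}

Timestamps are integer milliseconds, scene-relative and 0-based, on a strict
10 ms grid.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .scenes import ACTIVE_SCENES, ALL_SCENES, NEUTRAL_SCENES, scene_type

#: Internal marker for a missing pupil-diameter or eye-openness reading.
MISSING = float("nan")

#: On-disk sentinel for MISSING.
MISSING_SENTINEL = -1.0

#: Sampling period of the regular timeseries (100 Hz).
TICK_MS = 10

EVENT_KINDS = ("gaze_switch", "blink", "button", "survey")

SAMPLE_COLUMNS = [
    "t_ms",
    "gx", "gy", "gz",
    "hx", "hy", "hz",
    "fx", "fy", "fz",
    "pupil_l_mm", "pupil_r_mm",
    "open_l", "open_r",
    "object",
]


class LogValidationError(ValueError):
    """A session log violates a structural invariant."""


class LogParseError(ValueError):
    """A session-log file could not be parsed."""


def is_missing(value: float) -> bool:
    """True if ``value`` is the internal MISSING marker (NaN)."""
    return isinstance(value, float) and math.isnan(value)


@dataclass(frozen=True)
class SampleRecord:
    """One 10 ms tick of the tracker timeseries."""

    t_ms: int
    gaze_point: tuple[float, float, float]
    head_pos: tuple[float, float, float]
    head_fwd: tuple[float, float, float]
    pupil_l_mm: float = MISSING
    pupil_r_mm: float = MISSING
    openness_l: float = MISSING
    openness_r: float = MISSING
    object_name: str = ""


@dataclass(frozen=True)
class EventRecord:
    """A timestamped event with a kind-specific payload.

    Kinds: ``gaze_switch`` (payload: new object name), ``blink`` (running
    count + object of gaze at onset), ``button`` (button id, action, object of
    interaction), ``survey`` (scale name + integer value 0-100).
    """

    t_ms: int
    kind: str
    payload: Mapping = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise LogValidationError(f"unknown event kind {self.kind!r}")
        if self.kind == "survey":
            value = self.payload.get("value")
            if not isinstance(value, (int, np.integer)) or not 0 <= value <= 100:
                raise LogValidationError(
                    f"survey value must be an integer in [0, 100], got {value!r}"
                )


def samples_to_frame(records: list[SampleRecord]) -> pd.DataFrame:
    """Convert SampleRecords to the canonical samples DataFrame."""
    rows = []
    for r in records:
        rows.append(
            (r.t_ms, *r.gaze_point, *r.head_pos, *r.head_fwd,
             r.pupil_l_mm, r.pupil_r_mm, r.openness_l, r.openness_r,
             r.object_name)
        )
    df = pd.DataFrame(rows, columns=SAMPLE_COLUMNS)
    df["t_ms"] = df["t_ms"].astype(np.int64)
    return df


def frame_to_samples(df: pd.DataFrame) -> Iterator[SampleRecord]:
    """Iterate a samples DataFrame as SampleRecords."""
    for row in df.itertuples(index=False):
        yield SampleRecord(
            t_ms=int(row.t_ms),
            gaze_point=(row.gx, row.gy, row.gz),
            head_pos=(row.hx, row.hy, row.hz),
            head_fwd=(row.fx, row.fy, row.fz),
            pupil_l_mm=row.pupil_l_mm,
            pupil_r_mm=row.pupil_r_mm,
            openness_l=row.open_l,
            openness_r=row.open_r,
            object_name=row.object,
        )


@dataclass
class SceneSession:
    """One 5-minute scene: its 100 Hz samples and its event stream.

    ``samples`` is a DataFrame with :data:`SAMPLE_COLUMNS`; pupil and
    openness columns use NaN for MISSING and the ``object`` column uses the
    empty string when gaze is on no catalog object.
    """

    scene_name: str
    samples: pd.DataFrame
    events: list[EventRecord] = field(default_factory=list)
    duration_ms: int = 300_000

    @property
    def scene_type(self) -> str:
        return scene_type(self.scene_name)

    @property
    def duration_min(self) -> float:
        return self.duration_ms / 60_000.0


@dataclass
class ParticipantLog:
    """A full participant session: scene order, per-scene sessions, baselines."""

    participant_id: str
    scene_order: list[str]
    sessions: dict[str, SceneSession]
    baseline_surveys: dict[str, int] = field(default_factory=dict)


def validate_session(session: SceneSession) -> None:
    """Check all SceneSession/SampleRecord/EventRecord invariants.

    Raises :class:`LogValidationError` on the first violation found.
    """
    name = session.scene_name
    if name not in ALL_SCENES:
        raise LogValidationError(f"unknown scene name: {name!r}")
    df = session.samples
    missing_cols = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise LogValidationError(f"{name}: samples missing columns {missing_cols}")
    t = df["t_ms"].to_numpy()
    if len(t):
        if t[0] % TICK_MS != 0:
            raise LogValidationError(f"{name}: timestamps must be multiples of {TICK_MS} ms")
        dt = np.diff(t)
        if np.any(dt <= 0):
            i = int(np.argmax(dt <= 0))
            raise LogValidationError(
                f"{name}: non-monotone timestamps at row {i + 1} (t={t[i + 1]})"
            )
        if np.any(dt != TICK_MS):
            i = int(np.argmax(dt != TICK_MS))
            raise LogValidationError(
                f"{name}: samples off the {TICK_MS} ms grid at row {i + 1}"
            )
        if t[0] < 0 or t[-1] > session.duration_ms:
            raise LogValidationError(f"{name}: sample timestamps outside [0, duration]")
    for col in ("pupil_l_mm", "pupil_r_mm"):
        vals = df[col].to_numpy(dtype=float)
        present = ~np.isnan(vals)
        if np.any((vals[present] <= 0) | (vals[present] >= 10)):
            raise LogValidationError(f"{name}: {col} outside (0, 10) mm")
    for col in ("open_l", "open_r"):
        vals = df[col].to_numpy(dtype=float)
        present = ~np.isnan(vals)
        if np.any((vals[present] < 0) | (vals[present] > 1)):
            raise LogValidationError(f"{name}: {col} outside [0, 1]")
    fwd = df[["fx", "fy", "fz"]].to_numpy(dtype=float)
    if len(fwd):
        norms = np.linalg.norm(fwd, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise LogValidationError(f"{name}: head_fwd must have unit norm (1e-6)")
    last_t = -1
    for ev in session.events:
        if not 0 <= ev.t_ms <= session.duration_ms:
            raise LogValidationError(
                f"{name}: event at t={ev.t_ms} outside [0, {session.duration_ms}]"
            )
        if ev.t_ms < last_t:
            raise LogValidationError(f"{name}: events out of order at t={ev.t_ms}")
        last_t = ev.t_ms


def validate_log(log: ParticipantLog) -> None:
    """Check ParticipantLog invariants and every contained session."""
    order = log.scene_order
    if len(order) != 6 or len(set(order)) != 6:
        raise LogValidationError("scene_order must list 6 distinct scenes")
    if sorted(o for o in order if o in ACTIVE_SCENES) != sorted(ACTIVE_SCENES):
        raise LogValidationError("scene_order must contain the 3 Active scenes")
    if sorted(o for o in order if o in NEUTRAL_SCENES) != sorted(NEUTRAL_SCENES):
        raise LogValidationError("scene_order must contain the 3 Neutral scenes")
    for i, name in enumerate(order):
        want = "Active" if i % 2 == 0 else "Neutral"
        if scene_type(name) != want:
            raise LogValidationError(
                "scene_order must alternate Active/Neutral starting with Active"
            )
    for name, session in log.sessions.items():
        if name != session.scene_name:
            raise LogValidationError(
                f"sessions key {name!r} != session.scene_name {session.scene_name!r}"
            )
        if name not in order:
            raise LogValidationError(f"session {name!r} not in scene_order")
        validate_session(session)
    for key, value in log.baseline_surveys.items():
        if not isinstance(value, (int, np.integer)) or not 0 <= value <= 100:
            raise LogValidationError(
                f"baseline survey {key!r} must be an integer in [0, 100]"
            )


def _write_samples_csv(df: pd.DataFrame, path: Path) -> None:
    out = df.copy()
    for col in ("pupil_l_mm", "pupil_r_mm", "open_l", "open_r"):
        out[col] = out[col].astype(float).fillna(MISSING_SENTINEL)
    out.to_csv(path, index=False)


def _read_samples_csv(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype={"object": str}, keep_default_na=False,
                         na_values=["", "null"])
    except Exception as exc:  # pandas raises various parse errors
        raise LogParseError(f"{path}: {exc}") from exc
    missing_cols = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise LogParseError(f"{path}: missing columns {missing_cols}")
    for col in SAMPLE_COLUMNS:
        if col == "object":
            continue
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[col], errors="coerce")
            line = int(bad.index[bad.isna() & df[col].notna()][0]) + 2  # header + 1-based
            raise LogParseError(f"{path}:{line}: malformed value in column {col!r}") from exc
    try:
        df["t_ms"] = df["t_ms"].astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise LogParseError(f"{path}: non-integer timestamps") from exc
    for col in ("pupil_l_mm", "pupil_r_mm", "open_l", "open_r"):
        vals = df[col].astype(float)
        df[col] = vals.mask(vals == MISSING_SENTINEL, np.nan)
    df["object"] = df["object"].fillna("").astype(str)
    return df[SAMPLE_COLUMNS]


def _event_to_json(ev: EventRecord) -> str:
    return json.dumps({"t_ms": int(ev.t_ms), "kind": ev.kind,
                       "payload": dict(ev.payload)}, sort_keys=True)


def _read_events_jsonl(path: Path) -> list[EventRecord]:
    events = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                events.append(EventRecord(int(obj["t_ms"]), obj["kind"],
                                          obj.get("payload", {})))
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                raise LogParseError(f"{path}:{lineno}: malformed event: {exc}") from exc
    return events


def write_session_log(log: ParticipantLog, path: str | os.PathLike) -> None:
    """Write a ParticipantLog to ``path`` (a per-participant directory).

    The log must pass all invariants and contain at least one session.
    Missing pupil/openness readings are written as the ``-1.0`` sentinel.
    """
    if not log.sessions:
        raise LogValidationError("cannot write a log with no sessions")
    validate_log(log)
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    scenes_manifest = {}
    for name, session in log.sessions.items():
        samples_file = f"{name}_samples.csv"
        events_file = f"{name}_events.jsonl"
        _write_samples_csv(session.samples, root / samples_file)
        with open(root / events_file, "w") as fh:
            for ev in session.events:
                fh.write(_event_to_json(ev) + "\n")
        scenes_manifest[name] = {
            "samples": samples_file,
            "events": events_file,
            "duration_ms": int(session.duration_ms),
        }
    manifest = {
        "participant_id": log.participant_id,
        "scene_order": list(log.scene_order),
        "scenes": scenes_manifest,
        "baseline_surveys": {k: int(v) for k, v in log.baseline_surveys.items()},
    }
    with open(root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_session_log(path: str | os.PathLike) -> ParticipantLog:
    """Read a ParticipantLog from a per-participant directory.

    Normalizes on-disk MISSING encodings (``-1.0``, empty field, ``null``) to
    NaN, and validates all structural invariants.
    """
    root = Path(path)
    manifest_path = root / "manifest.json"
    if not manifest_path.exists():
        raise LogParseError(f"{manifest_path}: no manifest found")
    try:
        with open(manifest_path) as fh:
            manifest = json.load(fh)
    except json.JSONDecodeError as exc:
        raise LogParseError(f"{manifest_path}: {exc}") from exc
    sessions = {}
    for name, entry in manifest.get("scenes", {}).items():
        samples = _read_samples_csv(root / entry["samples"])
        events = _read_events_jsonl(root / entry["events"])
        sessions[name] = SceneSession(
            scene_name=name,
            samples=samples,
            events=events,
            duration_ms=int(entry["duration_ms"]),
        )
    log = ParticipantLog(
        participant_id=str(manifest["participant_id"]),
        scene_order=list(manifest["scene_order"]),
        sessions=sessions,
        baseline_surveys={k: int(v) for k, v in
                          manifest.get("baseline_surveys", {}).items()},
    )
    validate_log(log)
    return log
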