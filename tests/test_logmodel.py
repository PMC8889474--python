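"""Session-log data model: invariants, sentinel handling, round-trip I/O."""

import numpy as np
import pandas as pd
import pytest

from vreye.session import (
    EventRecord,
    LogParseError,
    LogValidationError,
    ParticipantLog,
    SceneSession,
    read_session_log,
    validate_log,
    validate_session,
    write_session_log,
)
from vreye.simulate import SimConfig, simulate_participant

from conftest import build_trace


def _tiny_log(samples=None, scene="Patio", events=None):
    samples = build_trace([4.0] * 10) if samples is None else samples
    order = ["Patio", "Library", "OutdoorBBQ", "Bus", "Driving", "WaitingRoom"]
    session = SceneSession(scene_name=scene, samples=samples,
                           events=events or [], duration_ms=1000)
    return ParticipantLog("p1", order, {scene: session}, {"mood": 40})


def test_roundtrip_identity_on_simulated_log(tmp_path, short_config):
    """read(write(log)) reproduces every field of a full simulated log."""
    log, _ = simulate_participant(short_config, 0)
    write_session_log(log, tmp_path / "p0")
    log2 = read_session_log(tmp_path / "p0")
    assert log2.participant_id == log.participant_id
    assert log2.scene_order == log.scene_order
    assert log2.baseline_surveys == log.baseline_surveys
    assert set(log2.sessions) == set(log.sessions)
    for name, session in log.sessions.items():
        other = log2.sessions[name]
        assert other.duration_ms == session.duration_ms
        pd.testing.assert_frame_equal(other.samples, session.samples,
                                      atol=1e-9, rtol=0)
        assert [(e.t_ms, e.kind, dict(e.payload)) for e in other.events] == \
               [(e.t_ms, e.kind, dict(e.payload)) for e in session.events]


def test_missing_sentinel_written_and_normalized(tmp_path):
    """MISSING pupils go to disk as -1.0 and come back as NaN."""
    pl = [4.0, np.nan, 4.1, np.nan]
    log = _tiny_log(build_trace(pl))
    write_session_log(log, tmp_path / "p")
    text = (tmp_path / "p" / "Patio_samples.csv").read_text()
    assert "-1.0" in text
    log2 = read_session_log(tmp_path / "p")
    back = log2.sessions["Patio"].samples["pupil_l_mm"].to_numpy()
    assert np.isnan(back[1]) and np.isnan(back[3])
    assert back[0] == 4.0


def test_reader_accepts_empty_and_null_as_missing(tmp_path):
    log = _tiny_log(build_trace([4.0, 4.0]))
    write_session_log(log, tmp_path / "p")
    path = tmp_path / "p" / "Patio_samples.csv"
    lines = path.read_text().splitlines()
    # blank out pupil_l on row 1, write 'null' for pupil_r on row 2
    cols = lines[0].split(",")
    il, ir = cols.index("pupil_l_mm"), cols.index("pupil_r_mm")
    row1 = lines[1].split(","); row1[il] = ""
    row2 = lines[2].split(","); row2[ir] = "null"
    path.write_text("\n".join([lines[0], ",".join(row1), ",".join(row2)]) + "\n")
    log2 = read_session_log(tmp_path / "p")
    samples = log2.sessions["Patio"].samples
    assert np.isnan(samples["pupil_l_mm"].iloc[0])
    assert np.isnan(samples["pupil_r_mm"].iloc[1])


def test_non_monotone_timestamps_rejected():
    samples = build_trace([4.0] * 5)
    samples.loc[3, "t_ms"] = 10  # duplicate/decreasing
    with pytest.raises(LogValidationError, match="monotone|grid"):
        validate_session(SceneSession("Patio", samples, [], 1000))


def test_off_grid_sampling_rejected():
    samples = build_trace([4.0] * 5)
    samples["t_ms"] = samples["t_ms"] * 2  # 20 ms spacing
    with pytest.raises(LogValidationError, match="grid"):
        validate_session(SceneSession("Patio", samples, [], 1000))


def test_unknown_scene_rejected():
    with pytest.raises(LogValidationError, match="unknown scene"):
        validate_session(SceneSession("Casino", build_trace([4.0]), [], 1000))


def test_pupil_range_enforced():
    samples = build_trace([12.0] * 3)
    with pytest.raises(LogValidationError, match="pupil"):
        validate_session(SceneSession("Patio", samples, [], 1000))


def test_head_fwd_must_be_unit():
    samples = build_trace([4.0] * 3)
    samples["fz"] = 0.5
    with pytest.raises(LogValidationError, match="unit"):
        validate_session(SceneSession("Patio", samples, [], 1000))


def test_empty_sessions_rejected_on_write(tmp_path):
    log = _tiny_log()
    log.sessions = {}
    with pytest.raises(LogValidationError, match="no sessions"):
        write_session_log(log, tmp_path / "p")


def test_scene_order_must_alternate():
    log = _tiny_log()
    log.scene_order = ["Patio", "OutdoorBBQ", "Library", "Bus", "Driving",
                       "WaitingRoom"]
    with pytest.raises(LogValidationError, match="alternate"):
        validate_log(log)


def test_survey_value_bounds():
    with pytest.raises(LogValidationError):
        EventRecord(0, "survey", {"scale": "craving", "value": 101})
    with pytest.raises(LogValidationError):
        EventRecord(0, "survey", {"scale": "craving", "value": 50.5})


def test_unknown_event_kind_rejected():
    with pytest.raises(LogValidationError):
        EventRecord(0, "teleport", {})


def test_malformed_csv_names_file_and_line(tmp_path):
    log = _tiny_log(build_trace([4.0, 4.0]))
    write_session_log(log, tmp_path / "p")
    path = tmp_path / "p" / "Patio_samples.csv"
    lines = path.read_text().splitlines()
    row = lines[2].split(",")
    row[0] = "oops"
    path.write_text("\n".join([lines[0], lines[1], ",".join(row)]) + "\n")
    with pytest.raises(LogParseError, match=r"samples\.csv"):
        read_session_log(tmp_path / "p")
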