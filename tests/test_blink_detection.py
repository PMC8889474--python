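"""Blink detection from missing-pupil runs: thresholds, partition, oracle."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from vreye.blinks import (
    BLINK_MAX_MS,
    BLINK_MIN_MS,
    BlinkEvent,
    EyeMode,
    classify_missing_runs,
    detect_blinks,
    summarize_blinks,
)
from vreye.scenes import BACKGROUND
from vreye.session import SceneSession, TICK_MS

from conftest import build_trace


def rle_oracle(missing):
    """Independent run-length-encoding classifier over a boolean sequence.

    Returns (blink_spans, n_short, n_long, n_truncated) where spans are
    (start_tick, n_ticks) for runs of 50-500 ms.
    """
    blinks, short, long_, truncated = [], 0, 0, 0
    pos = 0
    for val, group in itertools.groupby(missing):
        length = len(list(group))
        if val:
            if pos + length == len(missing):
                truncated += 1
            elif length * TICK_MS < BLINK_MIN_MS:
                short += 1
            elif length * TICK_MS > BLINK_MAX_MS:
                long_ += 1
            else:
                blinks.append((pos, length))
        pos += length
    return blinks, short, long_, truncated


def trace_with_run(n_missing, total=200, start=50):
    pl = np.full(total, 4.0)
    pl[start:start + n_missing] = np.nan
    return build_trace(pl)


@pytest.mark.parametrize(
    "n_ticks,expect_blink,expect_short,expect_long",
    [
        (20, 1, 0, 0),   # 200 ms -> blink
        (3, 0, 1, 0),    # 30 ms -> noise
        (70, 0, 0, 1),   # 700 ms -> microsleep
        (4, 0, 1, 0),    # 40 ms -> below threshold
        (5, 1, 0, 0),    # 50 ms -> inclusive lower bound
        (50, 1, 0, 0),   # 500 ms -> inclusive upper bound
        (51, 0, 0, 1),   # 510 ms -> above threshold
    ],
)
def test_duration_thresholds(n_ticks, expect_blink, expect_short, expect_long):
    cls = classify_missing_runs(trace_with_run(n_ticks))
    assert len(cls.blinks) == expect_blink
    assert cls.discarded_short == expect_short
    assert cls.discarded_long == expect_long
    if expect_blink:
        assert cls.blinks[0].duration_ms == n_ticks * TICK_MS
        assert cls.blinks[0].onset_ms == 50 * TICK_MS


def test_fully_present_trace_has_no_candidates():
    cls = classify_missing_runs(build_trace([4.0] * 100))
    assert cls.blinks == [] and cls.n_candidates == 0


def test_run_truncated_by_scene_end_counted_separately():
    pl = np.full(100, 4.0)
    pl[90:] = np.nan  # 100 ms run that reaches the last sample
    cls = classify_missing_runs(build_trace(pl))
    assert cls.blinks == []
    assert cls.discarded_truncated == 1


def test_monocular_dropout_modes():
    """One-eye missing is invisible under BOTH_EYES, a candidate under EITHER_EYE."""
    pl = np.full(100, 4.0)
    pr = np.full(100, 4.0)
    pl[40:47] = np.nan  # 70 ms, left eye only
    trace = build_trace(pl, pr)
    assert detect_blinks(trace, EyeMode.BOTH_EYES) == []
    events = detect_blinks(trace, EyeMode.EITHER_EYE)
    assert len(events) == 1 and events[0].duration_ms == 70


def test_object_at_onset_is_last_gazed_object():
    pl = np.full(60, 4.0)
    pl[30:40] = np.nan
    objects = ["lighter"] * 20 + [""] * 40
    events = detect_blinks(build_trace(pl, objects=objects))
    assert events[0].object_at_onset == "lighter"
    # no prior object at all -> BACKGROUND
    events = detect_blinks(build_trace(pl, objects=[""] * 60))
    assert events[0].object_at_onset == BACKGROUND


def test_off_grid_samples_rejected():
    trace = build_trace([4.0] * 10)
    trace["t_ms"] = trace["t_ms"] * 3
    with pytest.raises(ValueError, match="grid"):
        detect_blinks(trace)


def test_blink_event_duration_contract():
    with pytest.raises(ValueError):
        BlinkEvent(onset_ms=0, duration_ms=40)
    with pytest.raises(ValueError):
        BlinkEvent(onset_ms=0, duration_ms=510)


@given(st.lists(st.booleans(), min_size=1, max_size=400))
def test_partition_property(missing):
    """Every missing tick belongs to exactly one candidate and the tallies
    add up to the number of candidates."""
    missing = np.array(missing, dtype=bool)
    pl = np.where(missing, np.nan, 4.0)
    cls = classify_missing_runs(build_trace(pl))
    spans, short, long_, truncated = rle_oracle(missing)
    n_runs = short + long_ + truncated + len(spans)
    assert cls.n_candidates == n_runs
    assert (len(cls.blinks), cls.discarded_short, cls.discarded_long,
            cls.discarded_truncated) == (len(spans), short, long_, truncated)
    covered = np.zeros(len(missing), dtype=int)
    for start, length in spans:
        covered[start:start + length] += 1
    assert np.all(covered <= 1)


def test_random_traces_match_rle_oracle():
    """Random synthetic traces (dropouts, blinks, microsleeps) against the
    independent RLE oracle, both eye modes."""
    rng = np.random.default_rng(17)
    for _ in range(50):
        n = int(rng.integers(50, 1500))
        pl = np.full(n, 4.0)
        pr = np.full(n, 4.0)
        for arr in (pl, pr):
            for _ in range(rng.integers(0, 12)):
                start = int(rng.integers(0, n))
                length = int(rng.integers(1, 80))
                arr[start:start + length] = np.nan
        trace = build_trace(pl, pr)
        for mode, mask in ((EyeMode.BOTH_EYES, np.isnan(pl) & np.isnan(pr)),
                           (EyeMode.EITHER_EYE, np.isnan(pl) | np.isnan(pr))):
            cls = classify_missing_runs(trace, mode)
            spans, short, long_, truncated = rle_oracle(mask)
            got = [((e.onset_ms // TICK_MS), e.duration_ms // TICK_MS)
                   for e in cls.blinks]
            assert got == spans
            assert (cls.discarded_short, cls.discarded_long,
                    cls.discarded_truncated) == (short, long_, truncated)


def test_summary_rate_is_count_over_minutes():
    samples = build_trace([4.0] * 100)
    scene = SceneSession("Patio", samples, [], duration_ms=300_000)
    events = [BlinkEvent(i * 1000, 100) for i in range(150)]
    summary = summarize_blinks(events, scene)
    assert summary.ebr_per_min == 30.0
    assert summarize_blinks([], scene).ebr_per_min == 0.0


def test_simulated_blinks_recovered_exactly(short_config):
    """On simulated scenes, detected onsets/durations equal ground truth in
    both-eyes mode (closures never overlap by construction)."""
    from vreye.simulate import simulate_participant

    log, truth = simulate_participant(short_config, 1)
    for name, session in log.sessions.items():
        detected = [(e.onset_ms, e.duration_ms)
                    for e in detect_blinks(session.samples)]
        assert detected == truth.scenes[name].blinks
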