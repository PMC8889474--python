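"""Blink detection from runs of missing pupil-diameter samples.

The eye tracker reports no pupil diameter while the eyelid covers the pupil,
so an eyeblink appears in the 100 Hz timeseries as a contiguous run of
missing readings.  Each maximal run of missing samples is a *blink
candidate*; a candidate is classified by its duration:

* shorter than 50 ms — discarded as tracker noise,
* 50-500 ms inclusive — a blink (complete eyelid closure),
* longer than 500 ms — discarded as a microsleep.

Runs cut off by the end of the scene have undefined duration and are tallied
separately rather than classified.

Two candidate definitions are supported: under ``BOTH_EYES`` (the default) a
sample is missing only when both pupils are missing — complete eyelid closure
occludes both eyes, and monocular dropouts are tracker noise; under
``EITHER_EYE`` a sample with at least one missing pupil joins a candidate.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .scenes import BACKGROUND
from .session import SceneSession, TICK_MS

#: Minimum and maximum blink duration, inclusive, milliseconds.
BLINK_MIN_MS = 50
BLINK_MAX_MS = 500


class EyeMode(str, Enum):
    """Which eyes' missing readings define a blink candidate."""

    BOTH_EYES = "both"
    EITHER_EYE = "either"


@dataclass(frozen=True)
class BlinkEvent:
    """A detected blink: onset, duration, and the object gazed at onset."""

    onset_ms: int
    duration_ms: int
    object_at_onset: str = BACKGROUND

    def __post_init__(self):
        if not BLINK_MIN_MS <= self.duration_ms <= BLINK_MAX_MS:
            raise ValueError(
                f"blink duration must be in [{BLINK_MIN_MS}, {BLINK_MAX_MS}] ms, "
                f"got {self.duration_ms}"
            )


@dataclass
class RunClassification:
    """All missing-run candidates of a trace, classified by duration."""

    blinks: list[BlinkEvent]
    discarded_short: int
    discarded_long: int
    discarded_truncated: int

    @property
    def n_candidates(self) -> int:
        return (len(self.blinks) + self.discarded_short + self.discarded_long
                + self.discarded_truncated)


@dataclass
class BlinkSummary:
    """Per-scene blink accounting."""

    scene_name: str
    blink_count: int
    ebr_per_min: float
    discarded_short: int
    discarded_long: int
    discarded_truncated: int = 0


def missing_mask(samples: pd.DataFrame, mode: EyeMode = EyeMode.BOTH_EYES) -> np.ndarray:
    """Boolean mask of ticks that belong to a blink candidate under ``mode``."""
    miss_l = np.isnan(samples["pupil_l_mm"].to_numpy(dtype=float))
    miss_r = np.isnan(samples["pupil_r_mm"].to_numpy(dtype=float))
    if EyeMode(mode) is EyeMode.BOTH_EYES:
        return miss_l & miss_r
    return miss_l | miss_r


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in ``mask`` as (start, length) index pairs."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[0::2], edges[1::2]
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def _check_grid(t: np.ndarray) -> None:
    if t.size and (t[0] % TICK_MS != 0 or np.any(np.diff(t) != TICK_MS)):
        raise ValueError(f"samples must lie on the {TICK_MS} ms grid")


def _object_at_onset(objects: np.ndarray, start: int) -> str:
    """Last non-empty gazed object strictly before the run onset."""
    before = objects[:start]
    nonbg = np.flatnonzero(before != "")
    if nonbg.size == 0:
        return BACKGROUND
    return str(before[nonbg[-1]])


def classify_missing_runs(
    samples: pd.DataFrame, mode: EyeMode = EyeMode.BOTH_EYES
) -> RunClassification:
    """Partition the trace's missing ticks into classified candidates.

    Every missing tick (under ``mode``) belongs to exactly one candidate;
    ``blinks + discarded_short + discarded_long + discarded_truncated`` equals
    the number of candidates.
    """
    t = samples["t_ms"].to_numpy()
    _check_grid(t)
    mask = missing_mask(samples, mode)
    objects = samples["object"].to_numpy(dtype=object)
    n = mask.size
    blinks: list[BlinkEvent] = []
    short = long = truncated = 0
    for start, length in _runs(mask):
        if start + length == n:
            truncated += 1
            continue
        duration = length * TICK_MS
        if duration < BLINK_MIN_MS:
            short += 1
        elif duration > BLINK_MAX_MS:
            long += 1
        else:
            blinks.append(
                BlinkEvent(
                    onset_ms=int(t[start]),
                    duration_ms=duration,
                    object_at_onset=_object_at_onset(objects, start),
                )
            )
    return RunClassification(blinks, short, long, truncated)


def detect_blinks(
    samples: pd.DataFrame, mode: EyeMode = EyeMode.BOTH_EYES
) -> list[BlinkEvent]:
    """Detect blinks in a scene's samples.

    Returns disjoint, time-ordered :class:`BlinkEvent` objects whose duration
    is the missing-run length times the 10 ms sampling period.
    """
    return classify_missing_runs(samples, mode).blinks


def summarize_blinks(
    events: list[BlinkEvent],
    scene: SceneSession,
    mode: EyeMode = EyeMode.BOTH_EYES,
) -> BlinkSummary:
    """Per-scene blink count, per-minute rate (EBR), and discard tallies.

    ``events`` should come from :func:`detect_blinks` on ``scene.samples``;
    the discard tallies are recomputed from the samples under the same mode.
    """
    cls = classify_missing_runs(scene.samples, mode)
    return BlinkSummary(
        scene_name=scene.scene_name,
        blink_count=len(events),
        ebr_per_min=len(events) / scene.duration_min,
        discarded_short=cls.discarded_short,
        discarded_long=cls.discarded_long,
        discarded_truncated=cls.discarded_truncated,
    )
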