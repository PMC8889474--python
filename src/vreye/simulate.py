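"""Synthetic VR session generator with ground truth.

Generates :class:`~vreye.session.ParticipantLog` objects carrying the
statistical structure the analysis pipeline assumes, together with a
:class:`GroundTruth` record of every realized quantity, so that the entire
pipeline is testable — including parameter-recovery studies — with no
hardware and no data download.

Generative model, per scene:

* **Gaze** is a sequence of iid object dwell segments drawn proportionally to
  per-object selection weights (category weight x object attractiveness);
  consecutive segments on the same object merge, so the expected time share
  of each object is exactly its normalized weight.  The Active:Neutral
  category weight ratio is the scene's ``dwell_bias``.  Dwell segment
  durations are exponential with mean ``mean_dwell_ms``, truncated at 10 s.
* **Pupil diameter** per tick is the participant's baseline, plus
  ``pupil_cue_delta_mm`` while gaze rests on an Active-category object, plus
  iid per-eye Gaussian noise.
* **Eye closures** of three kinds interrupt the pupil signal: true blinks
  (uniform 50-500 ms durations), tracker dropouts (uniform 10-40 ms, may
  affect a single eye), and microsleeps (uniform 600-2000 ms).  Closures
  never overlap and keep at least a 2-tick gap, so detector recovery against
  ground truth is exact in both-eyes mode.  Both pupils go missing during
  blinks and microsleeps (physiological lid closure); dropouts hit the left
  eye, the right eye, or both.
* **Surveys**: post-scene craving ratings are condition mean + participant
  offset + scene noise, rounded and clipped to the 0-100 VAS range;
  relevance, baseline mood, and anxiety are truncated normals likewise.
* **Use history**: 90-day NTP use episodes are lognormal (matching the heavy
  right skew of the pilot sample: mean 772.29, SD 1008.20), and a positive
  ``use_episodes_slope`` couples a participant's dwell-bias multiplier to
  their (standardized log) use episodes.

A single global seed is fanned out to per-participant, per-scene substreams
through ``numpy.random.SeedSequence`` spawn keys, so adding participants or
scenes never perturbs existing ones.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .scenes import (
    ACTIVE,
    ACTIVE_SCENES,
    BACKGROUND_CAT,
    MISCELLANEOUS,
    NEUTRAL,
    NEUTRAL_SCENES,
    ObjectCatalog,
    make_scene_catalog,
)
from .session import (
    EventRecord,
    ParticipantLog,
    SceneSession,
    TICK_MS,
    SAMPLE_COLUMNS,
)

#: Default per-scene Active:Neutral dwell-weight ratios, set to the ratios of
#: the pilot sample's per-scene cue fixation-time means (Patio 4364:1962,
#: OutdoorBBQ 3061:2111, Driving 10238:34724 — the Driving scene reverses).
DEFAULT_DWELL_BIAS: dict[str, float] = {
    "Patio": 2.2,
    "OutdoorBBQ": 1.45,
    "Driving": 0.3,
}

_HEAD_POS = np.array([0.0, 1.6, 0.0])


class SimConfigError(ValueError):
    """A simulator configuration violates its constraints."""


@dataclass
class SimConfig:
    """Simulator configuration; defaults emulate the pilot study conditions."""

    seed: int = 0
    n_participants: int = 31
    scene_duration_ms: int = 300_000

    # gaze switch process
    dwell_bias: float | Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DWELL_BIAS)
    )
    mean_dwell_ms: float = 800.0
    max_dwell_ms: float = 10_000.0
    misc_weight: float = 0.6
    background_weight: float = 0.8

    #: SD of the per-participant lognormal multiplier on the Active dwell
    #: weight (individual differences in cue attentional capture).
    dwell_bias_sd_log: float = 0.5

    # pupil model (mm)
    pupil_base_mm: float = 4.0
    pupil_base_sd_mm: float = 0.6
    pupil_cue_delta_mm: float = -0.10
    #: per-participant SD of the cue-evoked diameter shift; 0.27 mm makes the
    #: pooled cue contrast carry a pilot-sized paired effect (|d| ~ 0.37).
    pupil_cue_delta_sd_mm: float = 0.27
    pupil_noise_sd_mm: float = 0.15

    # eye-closure processes (per-minute Poisson rates; uniform duration ranges)
    blink_rate_per_min: float = 20.0
    blink_dur_ms_range: tuple[float, float] = (50.0, 500.0)
    dropout_rate_per_min: float = 6.0
    dropout_dur_ms_range: tuple[float, float] = (10.0, 40.0)
    microsleep_rate_per_min: float = 0.2
    microsleep_dur_ms_range: tuple[float, float] = (600.0, 2000.0)

    # survey model (0-100 VAS)
    craving_active_mean: float = 42.77
    craving_neutral_mean: float = 29.42
    craving_sd: float = 21.5
    craving_between_sd: float = 25.0
    relevance_mean: float = 50.0
    relevance_sd: float = 20.0
    mood_mean: float = 35.0
    anxiety_mean: float = 30.0
    baseline_sd: float = 15.0

    # 90-day NTP use episodes (lognormal) and their coupling to dwell bias
    use_episodes_log_mean: float = 6.152
    use_episodes_log_sd: float = 0.997
    use_episodes_slope: float = 0.25

    #: Driving-reversal preset: categorize the Driving street-video panel as
    #: a Neutral cue (it is highly dwell-attractive) and leave the Driving
    #: object weights unbiased.
    driving_reversal: bool = False

    def scene_bias(self, scene_name: str) -> float:
        if isinstance(self.dwell_bias, Mapping):
            return float(self.dwell_bias.get(scene_name, 1.0))
        return float(self.dwell_bias)

    def validate(self) -> None:
        if self.n_participants < 0:
            raise SimConfigError("n_participants must be nonnegative")
        if self.scene_duration_ms <= 0 or self.scene_duration_ms % TICK_MS:
            raise SimConfigError("scene_duration_ms must be a positive multiple of 10")
        for name in ("mean_dwell_ms", "max_dwell_ms", "pupil_noise_sd_mm",
                     "pupil_cue_delta_sd_mm", "dwell_bias_sd_log",
                     "blink_rate_per_min", "dropout_rate_per_min",
                     "microsleep_rate_per_min", "craving_sd", "craving_between_sd"):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be nonnegative")
        lo, hi = self.blink_dur_ms_range
        if not (50 <= lo <= hi <= 500):
            raise SimConfigError("blink_dur_ms_range must lie within [50, 500]")
        lo, hi = self.dropout_dur_ms_range
        if not (0 < lo <= hi < 50):
            raise SimConfigError("dropout durations must lie in (0, 50)")
        lo, hi = self.microsleep_dur_ms_range
        if not (500 < lo <= hi):
            raise SimConfigError("microsleep durations must exceed 500 ms")
        biases = (self.dwell_bias.values()
                  if isinstance(self.dwell_bias, Mapping) else [self.dwell_bias])
        if any(b < 0 for b in biases):
            raise SimConfigError("dwell_bias must be nonnegative")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("blink_dur_ms_range", "dropout_dur_ms_range",
                    "microsleep_dur_ms_range"):
            d[key] = list(d[key])
        if isinstance(d["dwell_bias"], Mapping):
            d["dwell_bias"] = dict(d["dwell_bias"])
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SimConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        for key in ("blink_dur_ms_range", "dropout_dur_ms_range",
                    "microsleep_dur_ms_range"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        config = cls(**kwargs)
        config.validate()
        return config

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        path = Path(path)
        with open(path) as fh:
            data = (json.load(fh) if path.suffix == ".json"
                    else yaml.safe_load(fh))
        return cls.from_dict(data or {})

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            if path.suffix == ".json":
                json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            else:
                yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class SceneTruth:
    """Realized per-scene quantities recorded by the generator."""

    scene_name: str
    blinks: list[tuple[int, int]]            # (onset_ms, duration_ms)
    dropouts: list[tuple[int, int, str]]     # (onset_ms, duration_ms, eye)
    microsleeps: list[tuple[int, int]]
    dwell_totals_ms: dict[str, float]
    category_pupil_mean_mm: dict[str, float]
    craving: int = 0
    relevance: int = 0


@dataclass
class GroundTruth:
    """Per-participant generator record used as the recovery oracle."""

    participant_id: str
    use_episodes: float
    bias_multiplier: float
    pupil_base_mm: float
    cue_delta_mm: float
    craving_offset: float
    scenes: dict[str, SceneTruth] = field(default_factory=dict)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def draw_scene_order(seed: int) -> list[str]:
    """Pseudorandomize scenes within type, preserving the alternating
    Active, Neutral, Active, Neutral, Active, Neutral order."""
    rng = np.random.default_rng(seed)
    active = [str(s) for s in rng.permutation(ACTIVE_SCENES)]
    neutral = [str(s) for s in rng.permutation(NEUTRAL_SCENES)]
    order = []
    for a, n in zip(active, neutral):
        order.extend([a, n])
    return order


def _draw_order(rng: np.random.Generator) -> list[str]:
    active = [str(s) for s in rng.permutation(ACTIVE_SCENES)]
    neutral = [str(s) for s in rng.permutation(NEUTRAL_SCENES)]
    order = []
    for a, n in zip(active, neutral):
        order.extend([a, n])
    return order


def _vas(rng: np.random.Generator, mean: float, sd: float) -> int:
    return int(np.clip(np.rint(rng.normal(mean, sd)), 0, 100))


def _segment_weights(config: SimConfig, catalog: ObjectCatalog,
                     scene_name: str, bias_multiplier: float) -> np.ndarray:
    scene_bias = config.scene_bias(scene_name)
    if config.driving_reversal and scene_name == "Driving":
        scene_bias = 1.0
    cat_w = {
        ACTIVE: scene_bias * bias_multiplier,
        NEUTRAL: 1.0,
        MISCELLANEOUS: config.misc_weight,
        BACKGROUND_CAT: config.background_weight,
    }
    w = np.array([cat_w[e.category] * e.attractiveness for e in catalog])
    if not np.any(w > 0):
        raise SimConfigError(f"{scene_name}: all selection weights are zero")
    return w


def _draw_gaze_ticks(rng: np.random.Generator, config: SimConfig,
                     weights: np.ndarray, n_ticks: int) -> np.ndarray:
    """Per-tick catalog-entry index from the iid segment process."""
    cumw = np.cumsum(weights)
    total_w = cumw[-1]
    mean_ticks = max(config.mean_dwell_ms / TICK_MS, 1.0)
    max_ticks = max(int(config.max_dwell_ms / TICK_MS), 1)
    parts: list[np.ndarray] = []
    covered = 0
    while covered < n_ticks:
        m = max(int((n_ticks - covered) / mean_ticks * 1.5) + 16, 16)
        choices = np.searchsorted(cumw, rng.random(m) * total_w)
        durs = np.clip(np.rint(rng.exponential(mean_ticks, m)), 1, max_ticks)
        durs = durs.astype(np.int64)
        parts.append(np.repeat(choices, durs))
        covered += int(durs.sum())
    return np.concatenate(parts)[:n_ticks]


def _place_closures(rng: np.random.Generator, config: SimConfig,
                    n_ticks: int) -> tuple[list, list, list]:
    """Draw and place non-overlapping closures; returns (blinks, dropouts,
    microsleeps) as tick-space (onset, duration[, eye]) tuples."""
    minutes = n_ticks * TICK_MS / 60_000.0
    occupied = np.zeros(n_ticks, dtype=bool)

    def place(dur: int) -> int | None:
        if dur > n_ticks:
            return None
        for _ in range(500):
            onset = int(rng.integers(0, n_ticks - dur + 1))
            lo, hi = max(0, onset - 2), min(n_ticks, onset + dur + 2)
            if not occupied[lo:hi].any():
                occupied[lo:hi] = True
                return onset
        return None

    def dur_ticks(ms_range: tuple[float, float], lo: int, hi: int) -> int:
        return int(np.clip(np.rint(rng.uniform(*ms_range) / TICK_MS), lo, hi))

    microsleeps = []
    for _ in range(rng.poisson(config.microsleep_rate_per_min * minutes)):
        dur = dur_ticks(config.microsleep_dur_ms_range, 51, 10_000)
        onset = place(dur)
        if onset is not None:
            microsleeps.append((onset, dur))
    blinks = []
    for _ in range(rng.poisson(config.blink_rate_per_min * minutes)):
        dur = dur_ticks(config.blink_dur_ms_range, 5, 50)
        onset = place(dur)
        if onset is not None:
            blinks.append((onset, dur))
    dropouts = []
    for _ in range(rng.poisson(config.dropout_rate_per_min * minutes)):
        dur = dur_ticks(config.dropout_dur_ms_range, 1, 4)
        onset = place(dur)
        if onset is not None:
            u = rng.random()
            eye = "left" if u < 0.4 else ("right" if u < 0.8 else "both")
            dropouts.append((onset, dur, eye))
    return sorted(blinks), sorted(dropouts), sorted(microsleeps)


def _simulate_scene(
    rng: np.random.Generator,
    config: SimConfig,
    scene_name: str,
    catalog: ObjectCatalog,
    bias_multiplier: float,
    pupil_base: float,
    cue_delta: float | None = None,
) -> tuple[pd.DataFrame, list[EventRecord], SceneTruth]:
    if cue_delta is None:
        cue_delta = config.pupil_cue_delta_mm
    n_ticks = config.scene_duration_ms // TICK_MS
    names = np.array(catalog.names(), dtype=object)
    categories = np.array([e.category for e in catalog], dtype=object)
    positions = catalog.positions()

    weights = _segment_weights(config, catalog, scene_name, bias_multiplier)
    tick_idx = _draw_gaze_ticks(rng, config, weights, n_ticks)

    # gaze-switch events where the object changes (first segment at t=0)
    change = np.flatnonzero(np.diff(tick_idx)) + 1
    switch_ticks = np.concatenate(([0], change))
    events: list[EventRecord] = [
        EventRecord(int(tk) * TICK_MS, "gaze_switch",
                    {"object": str(names[tick_idx[tk]])})
        for tk in switch_ticks
    ]

    dwell_counts = np.bincount(tick_idx, minlength=len(catalog))
    dwell_totals = {str(names[i]): float(dwell_counts[i] * TICK_MS)
                    for i in range(len(catalog))}

    blinks_t, dropouts_t, microsleeps_t = _place_closures(rng, config, n_ticks)

    active_mask = categories[tick_idx] == ACTIVE
    mu = pupil_base + cue_delta * active_mask.astype(float)
    pl = np.clip(mu + rng.normal(0, config.pupil_noise_sd_mm, n_ticks), 0.1, 9.9)
    pr = np.clip(mu + rng.normal(0, config.pupil_noise_sd_mm, n_ticks), 0.1, 9.9)
    open_l = np.clip(rng.normal(0.95, 0.02, n_ticks), 0.0, 1.0)
    open_r = np.clip(rng.normal(0.95, 0.02, n_ticks), 0.0, 1.0)

    closure = np.zeros(n_ticks, dtype=bool)
    for onset, dur in blinks_t + microsleeps_t:
        closure[onset:onset + dur] = True
    pl[closure] = np.nan
    pr[closure] = np.nan
    open_l[closure] = 0.0
    open_r[closure] = 0.0
    for onset, dur, eye in dropouts_t:
        if eye in ("left", "both"):
            pl[onset:onset + dur] = np.nan
        if eye in ("right", "both"):
            pr[onset:onset + dur] = np.nan

    obj_pos = positions[tick_idx]
    gaze_point = obj_pos + rng.normal(0, 0.02, (n_ticks, 3))
    offsets = obj_pos - _HEAD_POS
    head_fwd = offsets / np.linalg.norm(offsets, axis=1, keepdims=True)

    for i, (onset, dur) in enumerate(blinks_t):
        events.append(EventRecord(onset * TICK_MS, "blink",
                                  {"count": i + 1,
                                   "object": str(names[tick_idx[onset]])}))
    events.sort(key=lambda ev: (ev.t_ms, 0 if ev.kind == "gaze_switch" else 1))

    samples = pd.DataFrame({
        "t_ms": np.arange(n_ticks, dtype=np.int64) * TICK_MS,
        "gx": gaze_point[:, 0], "gy": gaze_point[:, 1], "gz": gaze_point[:, 2],
        "hx": np.full(n_ticks, _HEAD_POS[0]),
        "hy": np.full(n_ticks, _HEAD_POS[1]),
        "hz": np.full(n_ticks, _HEAD_POS[2]),
        "fx": head_fwd[:, 0], "fy": head_fwd[:, 1], "fz": head_fwd[:, 2],
        "pupil_l_mm": pl, "pupil_r_mm": pr,
        "open_l": open_l, "open_r": open_r,
        "object": names[tick_idx],
    })[SAMPLE_COLUMNS]

    present_cats = set(categories)
    truth = SceneTruth(
        scene_name=scene_name,
        blinks=[(o * TICK_MS, d * TICK_MS) for o, d in blinks_t],
        dropouts=[(o * TICK_MS, d * TICK_MS, eye) for o, d, eye in dropouts_t],
        microsleeps=[(o * TICK_MS, d * TICK_MS) for o, d in microsleeps_t],
        dwell_totals_ms=dwell_totals,
        category_pupil_mean_mm={
            cat: pupil_base + (cue_delta if cat == ACTIVE else 0.0)
            for cat in present_cats
        },
    )
    return samples, events, truth


def scene_catalogs(config: SimConfig) -> dict[str, ObjectCatalog]:
    """The catalogs in force under ``config`` (honors the reversal preset)."""
    return {
        name: make_scene_catalog(
            name, driving_street_video_neutral=config.driving_reversal
        )
        for name in ACTIVE_SCENES + NEUTRAL_SCENES
    }


def simulate_participant(
    config: SimConfig, participant_index: int
) -> tuple[ParticipantLog, GroundTruth]:
    """Simulate one participant's full six-scene session.

    Deterministic given ``(config, participant_index)``: the log serializes
    byte-for-byte identically across calls.
    """
    config.validate()
    traits = _rng(config.seed, participant_index, 0)
    order = _draw_order(traits)
    pupil_base = float(np.clip(traits.normal(config.pupil_base_mm,
                                             config.pupil_base_sd_mm), 2.0, 7.0))
    z = traits.normal()
    log_episodes = config.use_episodes_log_mean + config.use_episodes_log_sd * z
    use_episodes = float(math.exp(log_episodes))
    bias_multiplier = float(math.exp(
        config.use_episodes_slope * z
        + config.dwell_bias_sd_log * traits.normal()))
    cue_delta = float(config.pupil_cue_delta_mm
                      + config.pupil_cue_delta_sd_mm * traits.normal())
    craving_offset = float(traits.normal(0.0, config.craving_between_sd))

    participant_id = f"sim-{participant_index:03d}"
    truth = GroundTruth(
        participant_id=participant_id,
        use_episodes=use_episodes,
        bias_multiplier=bias_multiplier,
        pupil_base_mm=pupil_base,
        cue_delta_mm=cue_delta,
        craving_offset=craving_offset,
    )
    catalogs = scene_catalogs(config)
    sessions: dict[str, SceneSession] = {}
    for slot, scene_name in enumerate(order, start=1):
        rng = _rng(config.seed, participant_index, slot)
        samples, events, scene_truth = _simulate_scene(
            rng, config, scene_name, catalogs[scene_name], bias_multiplier,
            pupil_base, cue_delta,
        )
        cond_mean = (config.craving_active_mean if scene_name in ACTIVE_SCENES
                     else config.craving_neutral_mean)
        craving = _vas(rng, cond_mean + craving_offset, config.craving_sd)
        relevance = _vas(rng, config.relevance_mean, config.relevance_sd)
        scene_truth.craving = craving
        scene_truth.relevance = relevance
        events.append(EventRecord(config.scene_duration_ms, "survey",
                                  {"scale": "craving", "value": craving}))
        events.append(EventRecord(config.scene_duration_ms, "survey",
                                  {"scale": "relevance", "value": relevance}))
        sessions[scene_name] = SceneSession(
            scene_name=scene_name, samples=samples, events=events,
            duration_ms=config.scene_duration_ms,
        )
        truth.scenes[scene_name] = scene_truth

    log = ParticipantLog(
        participant_id=participant_id,
        scene_order=order,
        sessions=sessions,
        baseline_surveys={
            "mood": _vas(traits, config.mood_mean, config.baseline_sd),
            "anxiety": _vas(traits, config.anxiety_mean, config.baseline_sd),
        },
    )
    return log, truth


def simulate_cohort(config: SimConfig) -> tuple[list[ParticipantLog], list[GroundTruth]]:
    """Simulate ``config.n_participants`` independent participants."""
    config.validate()
    logs, truths = [], []
    for i in range(config.n_participants):
        log, truth = simulate_participant(config, i)
        logs.append(log)
        truths.append(truth)
    return logs, truths


def simulate_survey_cohort(config: SimConfig, cohort_index: int = 0) -> pd.DataFrame:
    """Fast path: draw only the survey model for a cohort.

    Produces per-participant mean craving ratings over the three Active and
    three Neutral scenes under the same generative survey model as the full
    simulator (condition mean + participant offset + scene noise, rounded and
    clipped to 0-100), without any 100 Hz tick simulation.  Intended for
    calibration studies (type-I error, p-value uniformity, effect recovery)
    that need many replicate cohorts.
    """
    config.validate()
    rng = _rng(config.seed, 1_000_000 + cohort_index)
    n = config.n_participants
    offsets = rng.normal(0.0, config.craving_between_sd, size=(n, 1))
    active = np.clip(np.rint(
        config.craving_active_mean + offsets + rng.normal(0, config.craving_sd, (n, 3))
    ), 0, 100)
    neutral = np.clip(np.rint(
        config.craving_neutral_mean + offsets + rng.normal(0, config.craving_sd, (n, 3))
    ), 0, 100)
    return pd.DataFrame({
        "participant": [f"sim-{i:03d}" for i in range(n)],
        "craving_active": active.mean(axis=1),
        "craving_neutral": neutral.mean(axis=1),
    })
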