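"""In-task VAS aggregation and questionnaire scoring.

During the paradigm, a 0-100 visual analogue scale (VAS) for subjective
nicotine craving ("How much are you craving nicotine right now?") and scene
relevance is presented after each scene; depressed-mood and anxiety VAS
items are collected at baseline.  This module averages the post-scene
ratings over Active and Neutral scenes per participant.

Post-task questionnaires (presence, VR sickness) are scored with the generic
simple-averaging rule: the mean item response rescaled linearly to a 0-100
range.  Item wording and subscale membership are instrument-specific and are
supplied by the caller as item maps; only the averaging rule is fixed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .scenes import ACTIVE, NEUTRAL, scene_type
from .session import ParticipantLog


@dataclass
class SurveySummary:
    """Per-participant VAS aggregates (all values on the 0-100 scale)."""

    participant_id: str
    craving_active_mean: float | None = None
    craving_neutral_mean: float | None = None
    per_scene: dict[str, dict[str, float]] = field(default_factory=dict)
    baseline: dict[str, int] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


def aggregate_craving(log: ParticipantLog) -> SurveySummary:
    """Average post-scene craving ratings over Active and Neutral scenes.

    Expects exactly one craving survey event per scene; a scene with no
    rating is flagged and the mean is taken over the scenes that have one.
    """
    summary = SurveySummary(participant_id=log.participant_id,
                            baseline=dict(log.baseline_surveys))
    by_type: dict[str, list[float]] = {ACTIVE: [], NEUTRAL: []}
    for scene_name, session in log.sessions.items():
        ratings: dict[str, float] = {}
        for ev in session.events:
            if ev.kind == "survey":
                ratings[str(ev.payload.get("scale"))] = float(ev.payload["value"])
        summary.per_scene[scene_name] = ratings
        if "craving" in ratings:
            by_type[scene_type(scene_name)].append(ratings["craving"])
        else:
            summary.flags.append(f"missing craving rating for scene {scene_name}")
    if by_type[ACTIVE]:
        summary.craving_active_mean = sum(by_type[ACTIVE]) / len(by_type[ACTIVE])
    else:
        summary.flags.append("no Active-scene craving ratings")
    if by_type[NEUTRAL]:
        summary.craving_neutral_mean = sum(by_type[NEUTRAL]) / len(by_type[NEUTRAL])
    else:
        summary.flags.append("no Neutral-scene craving ratings")
    return summary


def score_average_scale(item_scores: Sequence[float], scale_max: float) -> float:
    """Simple-averaging questionnaire score on a 0-100 range.

    The mean of ``item_scores`` (each in ``[0, scale_max]``) rescaled
    linearly: ``100 * mean(items) / scale_max``.
    """
    if len(item_scores) == 0:
        raise ValueError("cannot score an empty item list")
    if scale_max <= 0:
        raise ValueError("scale_max must be positive")
    for v in item_scores:
        if not 0 <= v <= scale_max:
            raise ValueError(f"item score {v} outside [0, {scale_max}]")
    return 100.0 * (sum(item_scores) / len(item_scores)) / scale_max


def read_questionnaire_items(path: str | Path) -> pd.DataFrame:
    """Read questionnaire items from CSV: participant, instrument, item, value."""
    df = pd.read_csv(path)
    required = {"participant", "instrument", "item", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def score_questionnaires(
    items: pd.DataFrame, scale_max_by_instrument: dict[str, float]
) -> pd.DataFrame:
    """Score each (participant, instrument) block by simple averaging.

    ``scale_max_by_instrument`` gives the per-item maximum for each
    instrument (e.g. 6 for a 0-6 presence item); instruments absent from the
    map raise.  Returns one row per participant x instrument with the 0-100
    score and item count.
    """
    rows = []
    for (participant, instrument), block in items.groupby(["participant", "instrument"]):
        if instrument not in scale_max_by_instrument:
            raise ValueError(f"no scale_max given for instrument {instrument!r}")
        score = score_average_scale(
            block["value"].tolist(), scale_max_by_instrument[instrument]
        )
        rows.append({"participant": participant, "instrument": instrument,
                     "score": score, "n_items": len(block)})
    return pd.DataFrame(rows, columns=["participant", "instrument", "score", "n_items"])
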