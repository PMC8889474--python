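"""Per-participant metric extraction and cohort table assembly.

Bridges the raw session logs and the statistics battery: for each
participant it runs blink detection, fixation accounting, pupil aggregation,
and survey aggregation per scene, and flattens the results into one row of a
cohort DataFrame consumed by :func:`vreye.stats.run_contrast_table`.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .blinks import EyeMode, detect_blinks, summarize_blinks
from .fixations import accumulate_fixations, attentional_bias_score, fixation_indices
from .pupils import pupil_by_category
from .scenes import ACTIVE, ACTIVE_SCENES, NEUTRAL, ObjectCatalog, make_scene_catalog
from .session import ParticipantLog
from .surveys import aggregate_craving


def participant_metrics(
    log: ParticipantLog,
    catalogs: Mapping[str, ObjectCatalog] | None = None,
    mode: EyeMode = EyeMode.BOTH_EYES,
    margin_ms: int = 0,
    use_episodes: float | None = None,
) -> dict:
    """Flatten one participant's eye and survey metrics into a table row.

    Columns: ``craving_active``/``craving_neutral``; per Active scene
    ``fix_active_{scene}``/``fix_neutral_{scene}`` (total cue fixation, ms)
    and ``pupil_active_{scene}``/``pupil_neutral_{scene}`` (mean diameter,
    mm); ``blink_count_{scene}`` and ``ebr_per_min_{scene}`` for every scene
    present; ``bias_ms``; optionally ``use_episodes``.  Metrics that cannot
    be computed for a scene are NaN.
    """
    row: dict = {"participant": log.participant_id}
    survey = aggregate_craving(log)
    row["craving_active"] = (np.nan if survey.craving_active_mean is None
                             else survey.craving_active_mean)
    row["craving_neutral"] = (np.nan if survey.craving_neutral_mean is None
                              else survey.craving_neutral_mean)

    for scene_name, session in log.sessions.items():
        catalog = ((catalogs or {}).get(scene_name)
                   or make_scene_catalog(scene_name))
        blink_events = detect_blinks(session.samples, mode)
        summary = summarize_blinks(blink_events, session, mode)
        row[f"blink_count_{scene_name}"] = summary.blink_count
        row[f"ebr_per_min_{scene_name}"] = summary.ebr_per_min

        if scene_name in ACTIVE_SCENES:
            ledger = accumulate_fixations(session.events, catalog,
                                          session.duration_ms)
            indices = fixation_indices(ledger, session.duration_ms)
            row[f"fix_active_{scene_name}"] = indices.total_ms[ACTIVE]
            row[f"fix_neutral_{scene_name}"] = indices.total_ms[NEUTRAL]

            pupil = pupil_by_category(session.samples, blink_events, catalog,
                                      margin_ms=margin_ms, mode=mode,
                                      scene_name=scene_name)
            row[f"pupil_active_{scene_name}"] = pupil.mean_mm.get(ACTIVE, np.nan)
            row[f"pupil_neutral_{scene_name}"] = pupil.mean_mm.get(NEUTRAL, np.nan)

    try:
        row["bias_ms"] = attentional_bias_score(log, dict(catalogs or {})).bias_ms
    except ValueError:
        row["bias_ms"] = np.nan
    if use_episodes is not None:
        row["use_episodes"] = use_episodes
    return row


def cohort_table(
    logs: list[ParticipantLog],
    catalogs: Mapping[str, ObjectCatalog] | None = None,
    mode: EyeMode = EyeMode.BOTH_EYES,
    margin_ms: int = 0,
    use_episodes: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """One metrics row per participant, ready for the contrast battery.

    ``use_episodes`` optionally maps participant id to 90-day NTP use
    episodes (a self-report covariate, not derivable from the logs).
    """
    rows = [
        participant_metrics(
            log, catalogs=catalogs, mode=mode, margin_ms=margin_ms,
            use_episodes=(use_episodes or {}).get(log.participant_id),
        )
        for log in logs
    ]
    return pd.DataFrame(rows)
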