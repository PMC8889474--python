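"""Per-cue-category pupil-diameter aggregation.

Each valid 100 Hz sample contributes one diameter — the mean of whichever eye
values are present (binocular mean when both, monocular otherwise) — to the
cue category of the object gazed at that tick.  Samples are excluded when
they fall inside any missing-run candidate (blink, sub-50 ms dropout, or
microsleep) or within an optional guard margin around one, since diameters
adjacent to lid closure are occlusion-distorted.

Reported means are raw millimeters; no baseline correction or luminance
model is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .blinks import BlinkEvent, EyeMode, missing_mask, _check_grid, _runs
from .scenes import CATEGORIES, ObjectCatalog
from .session import TICK_MS


@dataclass
class PupilSummary:
    """Per-category mean pupil diameter for one scene.

    Categories with zero valid samples are absent from ``mean_mm`` (the mean
    is undefined, not zero).
    """

    scene_name: str
    mean_mm: dict[str, float] = field(default_factory=dict)
    n_samples: dict[str, int] = field(default_factory=dict)
    n_excluded: int = 0


def exclusion_mask(
    samples: pd.DataFrame,
    blink_events: list[BlinkEvent] | None = None,
    margin_ms: int = 0,
    mode: EyeMode = EyeMode.BOTH_EYES,
) -> np.ndarray:
    """Boolean mask of ticks excluded from pupil aggregation.

    Covers every missing-run candidate under ``mode`` (blinks and discarded
    candidates alike), any externally supplied blink events, and
    ``margin_ms`` of guard band on each side of each run.
    """
    t = samples["t_ms"].to_numpy()
    _check_grid(t)
    n = len(samples)
    mask = np.zeros(n, dtype=bool)
    margin_ticks = int(round(margin_ms / TICK_MS))
    t0 = int(t[0]) if n else 0
    spans = [(start, length) for start, length in _runs(missing_mask(samples, mode))]
    for ev in blink_events or []:
        spans.append(((ev.onset_ms - t0) // TICK_MS, ev.duration_ms // TICK_MS))
    for start, length in spans:
        lo = max(0, start - margin_ticks)
        hi = min(n, start + length + margin_ticks)
        mask[lo:hi] = True
    return mask


def pupil_by_category(
    samples: pd.DataFrame,
    blink_events: list[BlinkEvent] | None = None,
    catalog: ObjectCatalog | None = None,
    margin_ms: int = 0,
    mode: EyeMode = EyeMode.BOTH_EYES,
    scene_name: str = "",
) -> PupilSummary:
    """Mean pupil diameter per cue category over valid samples.

    Parameters
    ----------
    blink_events
        Blinks detected on these same samples; their spans are excluded (the
        missing-run candidates are recomputed and excluded as well, so
        passing ``None`` only drops the ability to widen externally detected
        spans).
    catalog
        Maps each sample's gazed object to its category; samples whose object
        is empty or not in the catalog contribute to no category.
    margin_ms
        Guard band excluded on each side of every missing run.
    """
    if catalog is None:
        raise ValueError("pupil_by_category requires an object catalog")
    excluded = exclusion_mask(samples, blink_events, margin_ms, mode)
    pl = samples["pupil_l_mm"].to_numpy(dtype=float)
    pr = samples["pupil_r_mm"].to_numpy(dtype=float)
    n_eyes = (~np.isnan(pl)).astype(int) + (~np.isnan(pr)).astype(int)
    total = np.where(np.isnan(pl), 0.0, pl) + np.where(np.isnan(pr), 0.0, pr)
    diameter = np.where(n_eyes > 0, total / np.maximum(n_eyes, 1), np.nan)
    no_eye = n_eyes == 0
    valid = ~excluded & ~no_eye

    objects = samples["object"].to_numpy(dtype=object)
    cat_by_obj = {e.name: e.category for e in catalog}
    summary = PupilSummary(scene_name=scene_name,
                           n_excluded=int((excluded | no_eye).sum()))
    sums = {c: 0.0 for c in CATEGORIES}
    counts = {c: 0 for c in CATEGORIES}
    # group valid ticks by object, then fold into categories
    for obj in pd.unique(objects[valid]):
        cat = cat_by_obj.get(obj)
        if cat is None:
            continue
        sel = valid & (objects == obj)
        sums[cat] += float(diameter[sel].sum())
        counts[cat] += int(sel.sum())
    for cat in CATEGORIES:
        if counts[cat] > 0:
            summary.mean_mm[cat] = sums[cat] / counts[cat]
            summary.n_samples[cat] = counts[cat]
    return summary
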