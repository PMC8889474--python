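"""Per-object fixation-time accounting and attentional-bias indices.

The paradigm's unit of "fixation" is the object-switch interval: every
``gaze_switch`` event opens a dwell segment on its object that closes at the
next switch (or at scene end for the final segment).  Segment durations are
accumulated per object into four category dictionaries (Active, Neutral,
Miscellaneous, Background); revisits add onto the same key.

From the ledger, two index families are derived per category: the *total*
fixation time (sum over the category's objects) and the *mean* fixation time
(total divided by the number of distinct objects gazed).  The attentional
bias score is the Active-minus-Neutral total fixation time, in milliseconds,
averaged over the three Active scenes; substance-cue attentional capture
shows up as a positive bias.

Time before the first gaze_switch event is assigned to no object and appears
only as uncovered time.  Miscellaneous and Background objects are accumulated
but excluded from Active-vs-Neutral cue contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .scenes import (
    ACTIVE,
    ACTIVE_SCENES,
    CATEGORIES,
    NEUTRAL,
    ObjectCatalog,
    make_scene_catalog,
)
from .session import EventRecord, ParticipantLog


@dataclass
class FixationLedger:
    """Four per-category mappings from object name to cumulative fixation ms."""

    by_category: dict[str, dict[str, float]] = field(
        default_factory=lambda: {c: {} for c in CATEGORIES}
    )

    def add(self, category: str, name: str, ms: float) -> None:
        mapping = self.by_category[category]
        mapping[name] = mapping.get(name, 0.0) + ms

    def total_ms(self, category: str) -> float:
        return sum(self.by_category[category].values())

    def n_objects(self, category: str) -> int:
        return len(self.by_category[category])

    def grand_total_ms(self) -> float:
        return sum(self.total_ms(c) for c in CATEGORIES)


@dataclass
class FixationIndices:
    """Totals, means, and the Active-minus-Neutral bias for one scene.

    ``mean_ms`` omits categories with no gazed objects (the mean is undefined
    there, not zero); ``bias_ms`` uses a zero total for an empty category.
    """

    total_ms: dict[str, float]
    mean_ms: dict[str, float]
    n_objects: dict[str, int]
    bias_ms: float


@dataclass
class BiasScore:
    """Participant-level attentional bias: mean per-scene bias over Active scenes."""

    bias_ms: float
    n_scenes: int
    per_scene_ms: dict[str, float]


def accumulate_fixations(
    events: list[EventRecord],
    catalog: ObjectCatalog,
    duration_ms: int,
) -> FixationLedger:
    """Accumulate gaze-switch events into a per-category fixation ledger.

    Each switch to object *o* at time *t* contributes ``t_next - t``
    milliseconds to *o*'s cumulative value, where ``t_next`` is the next
    switch time or ``duration_ms`` for the final segment.

    Raises ``ValueError`` for events out of ``[0, duration_ms]``, out of
    order, or naming an object absent from the catalog.
    """
    switches = [ev for ev in events if ev.kind == "gaze_switch"]
    ledger = FixationLedger()
    prev_t = None
    for ev in switches:
        if not 0 <= ev.t_ms <= duration_ms:
            raise ValueError(f"gaze_switch at t={ev.t_ms} outside [0, {duration_ms}]")
        if prev_t is not None and ev.t_ms < prev_t:
            raise ValueError(f"gaze_switch events out of order at t={ev.t_ms}")
        prev_t = ev.t_ms
        name = ev.payload.get("object")
        if name not in catalog:
            raise ValueError(f"gaze_switch names object {name!r} absent from catalog")
    for i, ev in enumerate(switches):
        t_next = switches[i + 1].t_ms if i + 1 < len(switches) else duration_ms
        name = ev.payload["object"]
        ledger.add(catalog.category_of(name), name, float(t_next - ev.t_ms))
    return ledger


def uncovered_ms(ledger: FixationLedger, duration_ms: int) -> float:
    """Scene time not attributed to any object (before the first switch)."""
    return duration_ms - ledger.grand_total_ms()


def fixation_indices(ledger: FixationLedger, duration_ms: int) -> FixationIndices:
    """Derive total/mean fixation-time indices and the cue bias from a ledger."""
    totals = {c: ledger.total_ms(c) for c in CATEGORIES}
    counts = {c: ledger.n_objects(c) for c in CATEGORIES}
    means = {c: totals[c] / counts[c] for c in CATEGORIES if counts[c] > 0}
    return FixationIndices(
        total_ms=totals,
        mean_ms=means,
        n_objects=counts,
        bias_ms=totals[ACTIVE] - totals[NEUTRAL],
    )


def attentional_bias_score(
    log: ParticipantLog,
    catalogs: dict[str, ObjectCatalog] | None = None,
) -> BiasScore:
    """Participant attentional-bias score in milliseconds.

    The mean over the three Active scenes of (Active-category total minus
    Neutral-category total) fixation time.  If an Active scene is missing
    from the log, the mean is taken over the available scenes and a warning
    is issued; the count of scenes used is reported.

    ``catalogs`` overrides the default scene catalogs (needed e.g. when the
    log was produced under the driving-reversal categorization).
    """
    per_scene: dict[str, float] = {}
    for scene_name in ACTIVE_SCENES:
        session = log.sessions.get(scene_name)
        if session is None:
            continue
        catalog = (catalogs or {}).get(scene_name) or make_scene_catalog(scene_name)
        ledger = accumulate_fixations(session.events, catalog, session.duration_ms)
        per_scene[scene_name] = fixation_indices(ledger, session.duration_ms).bias_ms
    if not per_scene:
        raise ValueError(f"participant {log.participant_id}: no Active scenes present")
    if len(per_scene) < len(ACTIVE_SCENES):
        warnings.warn(
            f"participant {log.participant_id}: attentional bias averaged over "
            f"{len(per_scene)}/3 Active scenes",
            stacklevel=2,
        )
    return BiasScore(
        bias_ms=sum(per_scene.values()) / len(per_scene),
        n_scenes=len(per_scene),
        per_scene_ms=per_scene,
    )


def estimate_dwell_bias(ledger: FixationLedger, catalog: ObjectCatalog) -> float:
    """Catalog-normalized Active:Neutral per-object mean dwell ratio.

    ``(total Active time / # Active objects in catalog) /
    (total Neutral time / # Neutral objects in catalog)`` — an unbiased
    estimator of the simulator's category dwell-weight ratio.
    """
    n_active = len(catalog.by_category(ACTIVE))
    n_neutral = len(catalog.by_category(NEUTRAL))
    if n_active == 0 or n_neutral == 0:
        raise ValueError("catalog must contain both Active and Neutral objects")
    neutral_rate = ledger.total_ms(NEUTRAL) / n_neutral
    if neutral_rate == 0:
        raise ValueError("no Neutral fixation time accumulated")
    return (ledger.total_ms(ACTIVE) / n_active) / neutral_rate
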