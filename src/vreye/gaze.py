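"""Gaze-to-object mapping with a manipulation lock.

Maps a gaze ray to the scene object being looked at.  The selector used here
is a documented geometric stand-in for the headset vendor's proprietary
learned gaze-to-object mapper: among catalog objects whose angular distance
from the gaze direction falls below a threshold (or below the angular radius
their selection sphere subtends, whichever is larger), it picks the object of
minimum angular distance.  Ties break by smaller Euclidean distance, then
lexicographic name, so selection is fully deterministic.

One behavioural rule from the paradigm is reproduced exactly: while a
participant holds a virtual object, selection is *locked* to that object —
the held object is reported as the gazed object regardless of geometry until
it is released.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .scenes import BACKGROUND, ObjectCatalog
from .session import EventRecord

#: Default angular selection threshold, degrees.
DEFAULT_ANGLE_THRESHOLD_DEG = 3.0


@dataclass(frozen=True)
class SelectionState:
    """Carries the manipulation lock across the event stream."""

    locked_object: str | None = None


def map_gaze_to_object(
    origin: np.ndarray,
    direction: np.ndarray,
    catalog: ObjectCatalog,
    state: SelectionState | None = None,
    angle_threshold_deg: float = DEFAULT_ANGLE_THRESHOLD_DEG,
) -> str:
    """Return the name of the gazed object, or :data:`BACKGROUND`.

    Parameters
    ----------
    origin
        Eye/head position, meters.
    direction
        Unit gaze direction (validated to 1e-6).
    state
        If ``state.locked_object`` is set, it is returned unconditionally.
    angle_threshold_deg
        Base angular gate in degrees, in (0, 15].  An object is eligible when
        its angular distance is within ``max(threshold, subtended radius)``.
    """
    if state is not None and state.locked_object is not None:
        if state.locked_object not in catalog:
            raise ValueError(f"locked object {state.locked_object!r} not in catalog")
        return state.locked_object
    direction = np.asarray(direction, dtype=float)
    origin = np.asarray(origin, dtype=float)
    norm = np.linalg.norm(direction)
    if abs(norm - 1.0) > 1e-6:
        raise ValueError(f"gaze direction must be unit-norm, got |d| = {norm:.6g}")
    if not 0 < angle_threshold_deg <= 15:
        raise ValueError("angle_threshold_deg must be in (0, 15]")
    if len(catalog) == 0:
        return BACKGROUND

    offsets = catalog.positions() - origin[None, :]
    dists = np.linalg.norm(offsets, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = (offsets @ direction) / dists
    cosang = np.clip(cosang, -1.0, 1.0)
    angles = np.degrees(np.arccos(cosang))
    # an object centered on the eye is trivially "hit"
    angles[dists == 0] = 0.0
    subtended = np.degrees(np.arcsin(np.clip(catalog.radii() / np.maximum(dists, 1e-12), 0.0, 1.0)))
    gate = np.maximum(angle_threshold_deg, subtended)
    eligible = np.flatnonzero(angles <= gate)
    if eligible.size == 0:
        return BACKGROUND
    names = catalog.names()
    best = min(eligible, key=lambda i: (angles[i], dists[i], names[i]))
    return names[best]


def update_lock(state: SelectionState, event: EventRecord) -> SelectionState:
    """Fold a button event into the selection lock.

    A ``pickup`` action locks selection to the manipulated object; ``release``
    clears the lock (idempotently); any other button leaves the state
    unchanged.
    """
    if event.kind != "button":
        raise ValueError(f"update_lock expects a button event, got {event.kind!r}")
    action = event.payload.get("action")
    if action == "pickup":
        obj = event.payload.get("object")
        if not obj:
            raise ValueError("pickup event must name the manipulated object")
        return replace(state, locked_object=obj)
    if action == "release":
        return replace(state, locked_object=None)
    return state
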