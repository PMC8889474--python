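"""Scene object catalogs for the six-scene VR cue-exposure paradigm.

The paradigm comprises three Active scenes containing nicotine and tobacco
product (NTP) cues (Driving, Patio, OutdoorBBQ) and three Neutral scenes with
only neutral objects (Bus, WaitingRoom, Library).  Every interactable or
gazeable object belongs to exactly one of four categories — Active, Neutral,
Miscellaneous, or Background — and fixation time is accumulated per category.

Object positions are in a right-handed coordinate frame, meters, with the
participant's head near the origin at eye height (y ~ 1.6 m).  Each object
carries a selection radius (the sphere used by the angular gaze selector) and
an ``attractiveness`` weight used only by the session simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ACTIVE = "Active"
NEUTRAL = "Neutral"
MISCELLANEOUS = "Miscellaneous"
BACKGROUND_CAT = "Background"
CATEGORIES = (ACTIVE, NEUTRAL, MISCELLANEOUS, BACKGROUND_CAT)

#: Sentinel returned by the gaze mapper when no catalog object is selected.
BACKGROUND = "BACKGROUND"

ACTIVE_SCENES = ("Driving", "Patio", "OutdoorBBQ")
NEUTRAL_SCENES = ("Bus", "WaitingRoom", "Library")
ALL_SCENES = ACTIVE_SCENES + NEUTRAL_SCENES


def scene_type(scene_name: str) -> str:
    """Return ``"Active"`` or ``"Neutral"`` for a known scene name."""
    if scene_name in ACTIVE_SCENES:
        return ACTIVE
    if scene_name in NEUTRAL_SCENES:
        return NEUTRAL
    raise ValueError(f"unknown scene name: {scene_name!r}")


@dataclass(frozen=True)
class ObjectEntry:
    """One named scene object: category, 3D position (m), selection radius (m).

    ``attractiveness`` is a per-object dwell weight multiplier used by the
    simulator's gaze switch process; it does not affect metric extraction.
    """

    name: str
    category: str
    position: tuple[float, float, float]
    radius: float
    attractiveness: float = 1.0

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r} for {self.name!r}")
        if not self.radius > 0:
            raise ValueError(f"radius must be > 0 for {self.name!r}")

    @property
    def pos(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


@dataclass
class ObjectCatalog:
    """Named scene objects with positions, selection radii, and cue categories."""

    entries: list[ObjectEntry] = field(default_factory=list)

    def __post_init__(self):
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("object names must be unique within a catalog")
        self._by_name = {e.name: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def get(self, name: str) -> ObjectEntry:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"object {name!r} not in catalog") from None

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def category_of(self, name: str) -> str:
        return self.get(name).category

    def by_category(self, category: str) -> list[ObjectEntry]:
        return [e for e in self.entries if e.category == category]

    def positions(self) -> np.ndarray:
        return np.array([e.position for e in self.entries], dtype=float)

    def radii(self) -> np.ndarray:
        return np.array([e.radius for e in self.entries], dtype=float)


# name, category, position, radius, attractiveness
_A, _N, _M, _B = ACTIVE, NEUTRAL, MISCELLANEOUS, BACKGROUND_CAT

_SCENE_OBJECTS: dict[str, list[tuple]] = {
    "Driving": [
        ("cigarette_pack", _A, (0.35, 1.05, 0.55), 0.07, 1.0),
        ("lighter", _A, (0.45, 1.05, 0.50), 0.05, 1.0),
        ("juul", _A, (0.25, 1.00, 0.60), 0.05, 1.0),
        ("ashtray", _A, (0.00, 1.00, 0.65), 0.08, 1.0),
        ("single_cigarette", _A, (-0.10, 1.02, 0.62), 0.05, 1.0),
        ("cellphone", _N, (-0.35, 1.05, 0.55), 0.07, 1.0),
        ("water_bottle", _N, (-0.45, 1.10, 0.45), 0.07, 1.0),
        ("coffee_cup", _N, (0.15, 1.08, 0.58), 0.06, 1.0),
        ("sunglasses", _N, (-0.25, 1.00, 0.60), 0.06, 1.0),
        ("passenger_model", _M, (0.75, 1.30, 0.30), 0.35, 1.0),
        ("car_radio", _M, (0.00, 1.10, 0.70), 0.10, 1.0),
        ("street_video", _B, (0.0, 2.0, 8.0), 4.00, 6.0),
        ("car_interior", _B, (0.0, 1.2, 1.5), 1.50, 1.0),
    ],
    "Patio": [
        ("hookah", _A, (1.20, 1.10, 2.10), 0.20, 1.0),
        ("ashtray", _A, (0.60, 0.95, 1.80), 0.08, 1.0),
        ("puffbar", _A, (0.75, 0.98, 1.85), 0.05, 1.0),
        ("cigarette_pack", _A, (0.90, 0.95, 1.90), 0.07, 1.0),
        ("lighter", _A, (1.00, 0.95, 1.95), 0.05, 1.0),
        ("candy_bowl", _N, (-0.70, 0.95, 1.85), 0.09, 1.0),
        ("magazine", _N, (-0.90, 0.95, 1.90), 0.10, 1.0),
        ("water_bottle", _N, (-0.55, 1.00, 1.80), 0.07, 1.0),
        ("pen", _N, (-1.05, 0.95, 1.95), 0.04, 1.0),
        ("smoking_model", _M, (2.00, 1.40, 2.60), 0.40, 1.0),
        ("patio_chair", _M, (-1.80, 0.80, 2.40), 0.40, 1.0),
        ("garden_wall", _B, (0.0, 1.8, 6.0), 3.00, 1.0),
        ("sky_panel", _B, (0.0, 6.0, 7.0), 4.00, 0.5),
    ],
    "OutdoorBBQ": [
        ("juul", _A, (0.80, 1.00, 2.00), 0.05, 1.0),
        ("single_cigarette", _A, (0.95, 1.00, 2.05), 0.05, 1.0),
        ("lighter", _A, (1.10, 1.00, 2.10), 0.05, 1.0),
        ("ashtray", _A, (0.65, 0.98, 1.95), 0.08, 1.0),
        ("hookah", _A, (1.60, 1.05, 2.40), 0.20, 1.0),
        ("water_bottle", _N, (-0.70, 1.00, 1.95), 0.07, 1.0),
        ("soda_can", _N, (-0.85, 1.00, 2.00), 0.06, 1.0),
        ("paper_plate", _N, (-0.55, 0.98, 1.90), 0.09, 1.0),
        ("napkins", _N, (-1.00, 0.98, 2.05), 0.07, 1.0),
        ("bbq_grill", _M, (2.20, 1.10, 2.80), 0.50, 1.0),
        ("vaping_model", _M, (-2.00, 1.40, 2.70), 0.40, 1.0),
        ("backyard_fence", _B, (0.0, 1.5, 6.5), 3.50, 1.0),
    ],
    "Bus": [
        ("cellphone", _N, (0.40, 1.05, 0.60), 0.07, 1.0),
        ("magazine", _N, (0.55, 1.05, 0.65), 0.10, 1.0),
        ("water_bottle", _N, (-0.40, 1.05, 0.60), 0.07, 1.0),
        ("candy_bar", _N, (-0.55, 1.02, 0.65), 0.05, 1.0),
        ("pen", _N, (0.25, 1.00, 0.58), 0.04, 1.0),
        ("umbrella", _N, (-0.25, 0.90, 0.62), 0.08, 1.0),
        ("passenger_model", _M, (1.00, 1.30, 1.20), 0.35, 1.0),
        ("bus_driver", _M, (0.60, 1.35, 3.00), 0.35, 1.0),
        ("bus_interior", _B, (0.0, 1.4, 2.0), 2.00, 1.0),
    ],
    "WaitingRoom": [
        ("magazine", _N, (0.60, 0.95, 1.50), 0.10, 1.0),
        ("cellphone", _N, (0.45, 0.95, 1.45), 0.07, 1.0),
        ("water_bottle", _N, (-0.50, 0.95, 1.50), 0.07, 1.0),
        ("pencil", _N, (-0.65, 0.95, 1.55), 0.04, 1.0),
        ("clipboard", _N, (-0.35, 0.95, 1.45), 0.09, 1.0),
        ("receptionist_model", _M, (1.50, 1.40, 2.80), 0.40, 1.0),
        ("potted_plant", _M, (-1.60, 1.00, 2.40), 0.30, 1.0),
        ("room_walls", _B, (0.0, 1.6, 4.5), 2.50, 1.0),
    ],
    "Library": [
        ("book", _N, (0.50, 1.00, 1.40), 0.08, 1.0),
        ("magazine", _N, (0.65, 1.00, 1.45), 0.10, 1.0),
        ("pen", _N, (0.35, 0.98, 1.38), 0.04, 1.0),
        ("water_bottle", _N, (-0.45, 1.00, 1.40), 0.07, 1.0),
        ("notebook", _N, (-0.60, 0.98, 1.45), 0.08, 1.0),
        ("librarian_model", _M, (1.80, 1.40, 3.00), 0.40, 1.0),
        ("bookshelf", _M, (-2.00, 1.50, 2.80), 0.60, 1.0),
        ("library_hall", _B, (0.0, 1.8, 5.0), 3.00, 1.0),
    ],
}


def make_scene_catalog(scene_name: str, driving_street_video_neutral: bool = False) -> ObjectCatalog:
    """Build the object catalog for one of the six scenes.

    Active scenes contain NTP cues (ashtrays, lighters, JUUL devices,
    cigarettes, Puffbars, hookahs) alongside neutral objects; Neutral scenes
    contain no Active-category objects.

    Parameters
    ----------
    scene_name
        One of ``Driving, Patio, OutdoorBBQ, Bus, WaitingRoom, Library``.
    driving_street_video_neutral
        The "driving-reversal" preset: recategorize the Driving scene's large
        street-video background panel as a Neutral cue.  The panel is highly
        dwell-attractive, so this preset pulls Neutral-category fixation time
        far above Active-category time in the Driving scene.
    """
    if scene_name not in _SCENE_OBJECTS:
        raise ValueError(f"unknown scene name: {scene_name!r}")
    entries = []
    for name, cat, pos, radius, attract in _SCENE_OBJECTS[scene_name]:
        if (
            driving_street_video_neutral
            and scene_name == "Driving"
            and name == "street_video"
        ):
            cat = NEUTRAL
        entries.append(ObjectEntry(name, cat, pos, radius, attract))
    return ObjectCatalog(entries)
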