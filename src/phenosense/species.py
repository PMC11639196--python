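"""Study species, phenophases and seasonal standardization windows.

Six widespread herbaceous species shared between Eurasia (native) and North
America (introduced). Three reproduce in spring and are standardized against
winter (January-March) climate; three reproduce in summer and are standardized
against spring (March-May) climate.
"""

from __future__ import annotations

SPRING_SPECIES: tuple[str, ...] = (
    "Tussilago farfara",
    "Ficaria verna",
    "Alliaria petiolata",
)

SUMMER_SPECIES: tuple[str, ...] = (
    "Cirsium arvense",
    "Daucus carota",
    "Lythrum salicaria",
)

SPECIES: tuple[str, ...] = SPRING_SPECIES + SUMMER_SPECIES

#: Phenophase labels in increasing reproductive order. Classification uses a
#: "latest stage wins" rule when several organ types are visible at once.
PHENOPHASES: tuple[str, ...] = ("vegetative", "budding", "flowering", "fruiting")

#: Phenophases retained for sensitivity modelling (vegetative records are
#: excluded during curation).
REPRODUCTIVE_PHENOPHASES: tuple[str, ...] = ("budding", "flowering", "fruiting")

CONTINENTS: tuple[str, ...] = ("Eurasia", "North America")

#: Month windows (inclusive month numbers) used to compute seasonal climate
#: for each blooming group: winter for spring bloomers, spring for summer
#: bloomers -- the season directly preceding the phenological event.
SEASON_WINDOWS: dict[str, tuple[int, int, int]] = {
    "spring": (1, 2, 3),
    "summer": (3, 4, 5),
}


def assign_season_group(species: str) -> str:
    """Return the blooming group ("spring" or "summer") of a study species.

    Raises
    ------
    ValueError
        If ``species`` is not one of the six study species.
    """
    if species in SPRING_SPECIES:
        return "spring"
    if species in SUMMER_SPECIES:
        return "summer"
    raise ValueError(
        f"unknown species {species!r}; expected one of {', '.join(SPECIES)}"
    )


def season_window(species: str) -> tuple[int, int, int]:
    """Months of the seasonal standardization window for a species."""
    return SEASON_WINDOWS[assign_season_group(species)]
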