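"""Reading, validation, classification and curation of phenology tables.

The observation CSV schema is fixed:

    id,species,date,latitude,longitude,continent,phenophase

with ISO dates, decimal-degree coordinates and phenophase one of vegetative /
budding / flowering / fruiting (empty when the record could not be
annotated). Curation applies the exclusion rules sequentially -- records
missing coordinates or date, unannotatable records, vegetative records, and
records inside configured excluded regions -- and reports a count for each
category, so a record failing several rules is counted once under the first.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .species import PHENOPHASES, SPECIES

CSV_COLUMNS = ("id", "species", "date", "latitude", "longitude", "continent", "phenophase")

#: Bounding boxes (lat_min, lat_max, lon_min, lon_max) for regions excluded
#: from analysis: outside the species' primary range, with records too sparse
#: to estimate sensitivity. The named regions are configurable.
DEFAULT_EXCLUDED_REGIONS: dict[str, tuple[float, float, float, float]] = {
    "Iceland": (63.0, 67.0, -25.0, -13.0),
    "Azores": (36.0, 40.0, -32.0, -24.0),
    "eastern Asia": (-10.0, 80.0, 90.0, 180.0),
    "Australia": (-45.0, -10.0, 110.0, 155.0),
}

#: Longitude east of this bound (and west of 90E) is treated as Eurasia when
#: a record lacks an explicit continent label.
CONTINENT_LON_SPLIT = -30.0


def classify_phenophase(has_bud: bool, has_flower: bool, has_fruit: bool) -> str:
    """Phenophase from organ flags; the latest visible stage wins."""
    if has_fruit:
        return "fruiting"
    if has_flower:
        return "flowering"
    if has_bud:
        return "budding"
    return "vegetative"


def day_of_year(date: _dt.date | str) -> int:
    """Ordinal day of year on a fixed 1-365 scale.

    Dec 31 of a leap year (ordinal day 366) is clamped to 365 so every
    calendar date maps into the 1-365 convention.
    """
    if isinstance(date, str):
        date = _dt.date.fromisoformat(date)
    return min(date.timetuple().tm_yday, 365)


def assign_continent(longitude: float) -> str:
    """Continent from longitude when the input table lacks the label."""
    return "North America" if longitude < CONTINENT_LON_SPLIT else "Eurasia"


@dataclass
class ExclusionReport:
    """Per-category record counts from sequential curation."""

    counts: dict[str, int] = field(default_factory=dict)
    n_input: int = 0
    n_retained: int = 0

    CATEGORIES = ("missing_meta", "unannotatable", "vegetative", "excluded_region")

    def to_frame(self) -> pd.DataFrame:
        rows = [{"category": c, "n_excluded": self.counts.get(c, 0)} for c in self.CATEGORIES]
        rows.append({"category": "retained", "n_excluded": self.n_retained})
        return pd.DataFrame(rows)

    def __str__(self) -> str:
        lines = [f"input records: {self.n_input}"]
        for c in self.CATEGORIES:
            lines.append(f"  excluded ({c}): {self.counts.get(c, 0)}")
        lines.append(f"retained: {self.n_retained}")
        return "\n".join(lines)


def read_observations(path) -> pd.DataFrame:
    """Read and validate an observation CSV."""
    df = pd.read_csv(path, dtype={"id": str, "species": str, "continent": str})
    return validate_observations(df)


def write_observations(df: pd.DataFrame, path) -> None:
    out = df.loc[:, list(CSV_COLUMNS)].copy()
    out.to_csv(path, index=False)


def validate_observations(df: pd.DataFrame) -> pd.DataFrame:
    """Check schema, ranges and labels; derive year and DOY columns.

    Missing coordinates/dates and missing phenophase are allowed (they are
    handled by :func:`filter_observations`); out-of-range values and unknown
    species or phenophase labels are errors.
    """
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"observation table is missing columns: {sorted(missing)}")
    df = df.copy()

    unknown = set(df["species"].dropna().unique()) - set(SPECIES)
    if unknown:
        raise ValueError(f"unknown species labels: {sorted(unknown)}")
    bad_phase = set(df["phenophase"].dropna().unique()) - set(PHENOPHASES)
    if bad_phase:
        raise ValueError(f"unknown phenophase labels: {sorted(bad_phase)}")

    lat = pd.to_numeric(df["latitude"], errors="coerce")
    lon = pd.to_numeric(df["longitude"], errors="coerce")
    if ((lat < -90) | (lat > 90)).any():
        raise ValueError("latitude outside [-90, 90]")
    if ((lon < -180) | (lon > 180)).any():
        raise ValueError("longitude outside [-180, 180]")
    df["latitude"] = lat
    df["longitude"] = lon

    dates = pd.to_datetime(df["date"], errors="raise", format="%Y-%m-%d")
    df["year"] = dates.dt.year
    df["doy"] = np.minimum(dates.dt.dayofyear, 365)

    blank = df["continent"].isna() & df["longitude"].notna()
    if blank.any():
        df["continent"] = df["continent"].astype(object)
        df.loc[blank, "continent"] = df.loc[blank, "longitude"].map(assign_continent)
    return df


def _in_region(df: pd.DataFrame, box: tuple[float, float, float, float]) -> pd.Series:
    lat_min, lat_max, lon_min, lon_max = box
    return (
        df["latitude"].between(lat_min, lat_max)
        & df["longitude"].between(lon_min, lon_max)
    )


def filter_observations(
    df: pd.DataFrame,
    excluded_regions: dict[str, tuple[float, float, float, float]] | None = None,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the curation rules sequentially; return retained table + report.

    Order: missing coordinates/date, unannotatable phenophase, vegetative
    records, excluded regions. The retained count plus the per-category
    excluded counts always equals the input count.
    """
    if excluded_regions is None:
        excluded_regions = DEFAULT_EXCLUDED_REGIONS
    unknown = set(df["species"].dropna().unique()) - set(SPECIES)
    if unknown:
        raise ValueError(f"unknown species labels: {sorted(unknown)}")

    report = ExclusionReport(n_input=len(df))
    kept = df

    missing_meta = (
        kept["latitude"].isna() | kept["longitude"].isna() | kept["date"].isna()
    )
    report.counts["missing_meta"] = int(missing_meta.sum())
    kept = kept[~missing_meta]

    unannotatable = kept["phenophase"].isna()
    report.counts["unannotatable"] = int(unannotatable.sum())
    kept = kept[~unannotatable]

    vegetative = kept["phenophase"] == "vegetative"
    report.counts["vegetative"] = int(vegetative.sum())
    kept = kept[~vegetative]

    in_excluded = pd.Series(False, index=kept.index)
    for box in excluded_regions.values():
        in_excluded |= _in_region(kept, box)
    report.counts["excluded_region"] = int(in_excluded.sum())
    kept = kept[~in_excluded]

    report.n_retained = len(kept)
    return kept.copy(), report
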