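"""Visual-census data model, density arithmetic and CSV exchange.

A stationary visual census records every individual of the target species
within a fixed radius around a diver: juveniles (total length <= 10 cm)
within r = 2 m and adults within r = 4 m.  Density per census is
``count / (pi * r^2)``.  Surveys are exchanged as flat CSV tables with one
row per (census, life stage) and a companion per-site covariate table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

LIFE_STAGES = ("juvenile", "adult")
MPA_REGIMES = ("no-take", "multiple-use", "open")

#: default census radius (m) per life stage
STAGE_RADIUS_M = {"juvenile": 2.0, "adult": 4.0}

#: total length (cm) at or below which an individual counts as a juvenile
JUVENILE_MAX_LENGTH_CM = 10.0

SURVEY_COLUMNS = [
    "site_id", "location", "mpa_regime", "year",
    "observer_id", "life_stage", "radius_m", "count",
]

SITE_COLUMNS = [
    "site_id", "x_km", "y_km",
    "turf", "cca", "fire_coral", "macroalgae", "sponge", "stony_coral",
    "zoanthid", "sst_c", "sss_psu", "depth_m", "rugosity", "dist_land_m",
]

BENTHIC_COVERS = ["turf", "cca", "fire_coral", "macroalgae", "sponge",
                  "stony_coral", "zoanthid"]


class SchemaError(ValueError):
    """A CSV table is missing a mandatory column or violates the schema."""


@dataclass(frozen=True)
class CensusRecord:
    """One stationary visual census for one life stage."""

    site_id: str
    location: str
    mpa_regime: str
    year: int
    observer_id: str
    life_stage: str
    radius_m: float
    count: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError(f"count must be >= 0, got {self.count}")
        if self.radius_m <= 0:
            raise ValueError(f"radius_m must be > 0, got {self.radius_m}")
        if self.life_stage not in LIFE_STAGES:
            raise ValueError(f"unknown life_stage {self.life_stage!r}")


@dataclass(frozen=True)
class SiteCovariates:
    """Benthic and environmental predictors for one reef site."""

    site_id: str
    x_km: float
    y_km: float
    turf: float
    cca: float
    fire_coral: float
    macroalgae: float
    sponge: float
    stony_coral: float
    zoanthid: float
    sst_c: float
    sss_psu: float
    depth_m: float
    rugosity: int
    dist_land_m: float

    def __post_init__(self) -> None:
        covers = [getattr(self, c) for c in BENTHIC_COVERS]
        if any(not 0.0 <= c <= 1.0 for c in covers):
            raise ValueError("benthic cover fractions must lie in [0, 1]")
        if sum(covers) > 1.0 + 1e-9:
            raise ValueError("benthic cover fractions must sum to <= 1")
        if self.rugosity not in (0, 1):
            raise ValueError("rugosity must be 0 or 1")


def census_area(radius_m: float) -> float:
    """Sampled area pi*r^2 (m^2) of a stationary census of radius ``radius_m``."""
    if radius_m <= 0:
        raise ValueError(f"radius_m must be > 0, got {radius_m}")
    return math.pi * radius_m ** 2


def printed_area(radius_m: float, decimals: int = 1) -> float:
    """Census area as printed in survey protocols (12.6 m^2 at r=2, 50.2 at r=4).

    Protocol tables follow the field shorthand pi ~ 3.14 before rounding to
    one decimal, which is how 50.27 m^2 appears as 50.2: 3.14 * 16 = 50.24.
    Exact geometry lives in :func:`census_area`; this helper only reproduces
    the display convention.
    """
    return round(3.14 * radius_m ** 2, decimals)


def census_density(count: int, radius_m: float) -> float:
    """Individuals per census area: ``count / (pi * r^2)``."""
    if count < 0:
        raise ValueError(f"count must be >= 0, got {count}")
    return count / census_area(radius_m)


def classify_individual(total_length_cm: float,
                        threshold_cm: float = JUVENILE_MAX_LENGTH_CM) -> str:
    """Life stage from total length: juvenile iff length <= threshold (10 cm)."""
    if total_length_cm <= 0:
        raise ValueError(f"total_length_cm must be > 0, got {total_length_cm}")
    return "juvenile" if total_length_cm <= threshold_cm else "adult"


def _as_frame(records: Iterable[CensusRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        missing = [c for c in SURVEY_COLUMNS if c not in records.columns]
        if missing:
            raise SchemaError(f"survey table missing columns: {missing}")
        return records
    return pd.DataFrame([r.__dict__ for r in records], columns=SURVEY_COLUMNS)


def aggregate_mean_density(records: Iterable[CensusRecord] | pd.DataFrame,
                           group_by: str = "location",
                           life_stage: str | None = None,
                           per_m2: bool = False) -> pd.Series:
    """Mean density per group: total individuals / number of censuses.

    With ``per_m2=True`` each census count is first divided by its sampled
    area so the mean is in individuals per m^2.  Groups with no censuses are
    absent from the result (missing, never reported as zero).
    """
    df = _as_frame(records)
    if life_stage is not None:
        df = df[df["life_stage"] == life_stage]
    if per_m2:
        values = df["count"] / (np.pi * df["radius_m"] ** 2)
    else:
        values = df["count"].astype(float)
    return values.groupby(df[group_by]).mean()


def densities(records: Iterable[CensusRecord] | pd.DataFrame) -> pd.DataFrame:
    """Per-census density table: the survey columns plus area_m2 and density."""
    df = _as_frame(records).copy()
    df["area_m2"] = np.pi * df["radius_m"] ** 2
    df["density"] = df["count"] / df["area_m2"]
    return df


def read_survey_csv(path: str | Path) -> pd.DataFrame:
    """Read a survey table, validating the schema.

    Raises :class:`SchemaError` when a mandatory column is absent and a
    ``ValueError`` naming the offending row when a count is not an integer.
    Unknown columns are preserved untouched.
    """
    df = pd.read_csv(path)
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = df.index[counts.isna() | (counts != counts.round())]
    if len(bad):
        raise ValueError(
            f"{path}: non-integer count at row(s) {list(bad[:5])} "
            f"(first offending value: {df.loc[bad[0], 'count']!r})")
    if (counts < 0).any():
        row = int(df.index[counts < 0][0])
        raise ValueError(f"{path}: negative count at row {row}")
    df["count"] = counts.astype(int)
    df["year"] = df["year"].astype(int)
    df["radius_m"] = df["radius_m"].astype(float)
    return df


def write_survey_csv(records: Iterable[CensusRecord] | pd.DataFrame,
                     path: str | Path) -> None:
    _as_frame(records).to_csv(path, index=False)


def read_sites_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    return df


def write_sites_csv(sites: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in SITE_COLUMNS if c not in sites.columns]
    if missing:
        raise SchemaError(f"site table missing columns: {missing}")
    sites.to_csv(path, index=False)


def records_from_frame(df: pd.DataFrame) -> list[CensusRecord]:
    """Materialise validated :class:`CensusRecord` objects from a table."""
    names = [f.name for f in fields(CensusRecord)]
    return [CensusRecord(**{n: row[n] for n in names})
            for row in df[names].to_dict("records")]
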