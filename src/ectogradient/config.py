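"""Study configuration, site table handling and deterministic seeding.

The study grid is a fixed set of 15 field sites in the northern Dinaric
Mountains / south-eastern Alps spanning ~240–1280 m a.s.l., classified by
which of the two lizard species occurs there: both (*syntopy*) or only one
(*allotopy*).  The built-in site table ships with the package; user site
tables are plain CSV with the same columns.

All randomness in the pipeline flows from ``StudyConfig.rng_seed`` through
:func:`site_seed_sequences`, so equal configurations give bit-identical
trait tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

OCCURRENCE_CLASSES = ("syntopy", "allotopy_horvathi", "allotopy_muralis")

#: label printed in the field table for each occurrence class
OCCURRENCE_DISPLAY = {
    "syntopy": "Both",
    "allotopy_horvathi": "I. horvathi",
    "allotopy_muralis": "P. muralis",
}

HOURS_PER_DAY = 24
DAYS_PER_YEAR = 365  # no leap days: every simulated year has 365 days


class ConfigError(ValueError):
    """Raised for malformed site tables or study configurations."""


@dataclass(frozen=True)
class SiteSpec:
    """A single study site.

    Parameters
    ----------
    name : str
        Site name.
    lat, lon : float
        Geographic coordinates, degrees north / east.
    elevation : float
        Metres above sea level; must lie in [0, 3000].
    occurrence : str
        One of ``syntopy``, ``allotopy_horvathi``, ``allotopy_muralis``.
    """

    name: str
    lat: float
    lon: float
    elevation: float
    occurrence: str

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0):
            raise ConfigError(f"site {self.name!r}: lat {self.lat} outside [-90, 90]")
        if not (0.0 <= self.elevation <= 3000.0):
            raise ConfigError(
                f"site {self.name!r}: elevation {self.elevation} outside [0, 3000]"
            )
        if self.occurrence not in OCCURRENCE_CLASSES:
            raise ConfigError(
                f"site {self.name!r}: unknown occurrence {self.occurrence!r}; "
                f"allowed: {', '.join(OCCURRENCE_CLASSES)}"
            )

    @property
    def occurrence_display(self) -> str:
        return OCCURRENCE_DISPLAY[self.occurrence]


@dataclass
class StudyConfig:
    """Settings shared by the whole simulation pipeline.

    Defaults reproduce the study conditions: a 16-year hourly microclimate
    horizon, oviposition on day-of-year 140 with the egg buried 5 cm below
    ground, shade selection between 0 and 90 %, and a reproductive season
    bounded by the 12.6 h (opening, spring) and 14 h (closing, late summer)
    photoperiod thresholds.
    """

    start_year: int = 1995
    n_years: int = 16
    start_doy: int = 140
    egg_depth: float = 5.0
    repro_photoperiod_open: float = 12.6
    repro_photoperiod_close: float = 14.0
    season_set: str = "spring"
    rng_seed: int = 1
    shade_levels: list = field(
        default_factory=lambda: [round(0.1 * i, 1) for i in range(10)]
    )
    depth_grid: list = field(
        default_factory=lambda: [0.0, 2.5, 5.0, 10.0, 20.0, 50.0, 100.0, 200.0]
    )

    def __post_init__(self) -> None:
        if int(self.n_years) < 1:
            raise ConfigError(f"n_years must be >= 1, got {self.n_years}")
        if not (1 <= int(self.start_doy) <= 365):
            raise ConfigError(f"start_doy must be in [1, 365], got {self.start_doy}")
        if self.season_set not in ("spring", "summer"):
            raise ConfigError(f"season_set must be 'spring' or 'summer', got {self.season_set!r}")
        if any(s < 0.0 or s > 0.9 for s in self.shade_levels):
            raise ConfigError("shade_levels must lie within [0, 0.9]")
        if len(self.depth_grid) == 0:
            raise ConfigError("depth_grid must not be empty")
        if any(d < 0 for d in self.depth_grid):
            raise ConfigError("depths must be >= 0")

    @property
    def n_hours(self) -> int:
        return int(self.n_years) * DAYS_PER_YEAR * HOURS_PER_DAY


_NUMERIC_FIELDS = {
    "start_year", "n_years", "start_doy", "egg_depth",
    "repro_photoperiod_open", "repro_photoperiod_close", "rng_seed",
}


def load_config(yaml_path) -> StudyConfig:
    """Read a :class:`StudyConfig` from YAML; missing keys take defaults.

    Unknown keys and non-numeric values for numeric fields raise
    :class:`ConfigError` — no silent ignoring.
    """
    with open(yaml_path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {yaml_path} must contain a mapping")
    known = {f.name for f in dataclasses.fields(StudyConfig)}
    for key, value in raw.items():
        if key not in known:
            raise ConfigError(f"unknown config key {key!r}")
        if key in _NUMERIC_FIELDS and not isinstance(value, (int, float)):
            raise ConfigError(f"config key {key!r} must be numeric, got {value!r}")
        if key in ("shade_levels", "depth_grid"):
            if not isinstance(value, (list, tuple)) or any(
                not isinstance(v, (int, float)) for v in value
            ):
                raise ConfigError(f"config key {key!r} must be a list of numbers")
    return StudyConfig(**raw)


def load_sites(source: str | Path = "builtin") -> list[SiteSpec]:
    """Load study sites from a CSV file or the built-in field table.

    The built-in table has 15 rows arranged by increasing elevation,
    five per occurrence class.
    """
    if source == "builtin":
        with resources.files("ectogradient.data").joinpath("sites.csv").open(
            "r", encoding="utf-8"
        ) as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(source)
    required = ["name", "lat", "lon", "elevation", "occurrence"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigError(f"site table missing columns: {missing}")
    if len(df) == 0:
        raise ConfigError("no sites in table")
    sites = []
    for i, row in df.iterrows():
        try:
            sites.append(
                SiteSpec(
                    name=str(row["name"]),
                    lat=float(row["lat"]),
                    lon=float(row["lon"]),
                    elevation=float(row["elevation"]),
                    occurrence=str(row["occurrence"]),
                )
            )
        except (TypeError, ValueError) as exc:
            if isinstance(exc, ConfigError):
                raise
            raise ConfigError(f"malformed site row {i}: {exc}") from exc
    names = [s.name for s in sites]
    if len(set(names)) != len(names):
        raise ConfigError("duplicate site names in table")
    return sites


def sites_to_frame(sites: list[SiteSpec]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "name": [s.name for s in sites],
            "lat": [s.lat for s in sites],
            "lon": [s.lon for s in sites],
            "elevation": [s.elevation for s in sites],
            "occurrence": [s.occurrence for s in sites],
        }
    )


def write_traits(table: pd.DataFrame, csv_path) -> None:
    """Write a trait table as comma-separated UTF-8 CSV with a header row."""
    table.to_csv(csv_path, index=False, encoding="utf-8")


def read_traits(csv_path) -> pd.DataFrame:
    return pd.read_csv(csv_path, encoding="utf-8")


def site_seed_sequences(seed: int, n: int) -> list[np.random.SeedSequence]:
    """Spawn one independent seed sequence per site from the study seed."""
    return np.random.SeedSequence(int(seed)).spawn(n)
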