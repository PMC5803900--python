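"""Core domain types, validation, and CSV interchange.

The analysis discretizes an elevational gradient into fixed-width bands
(100 vertical meters by default) and treats each species as an elevational
occupancy interval.  Everything downstream — interpolated richness, the
mid-domain-effect null model, the augmentation sensitivity analysis, and the
band-level regressions — operates on these two objects plus a per-band
covariate table (land area and human population density).

Bands are half-open intervals ``(label - band_width, label]`` identified by
their **upper** edge, so under the default grid the band labels run
100, 200, ..., 4900.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TAXON_CLASSES = ("Mammalia", "Aves", "Reptilia", "Amphibia", "Actinopterygii", "other")
IUCN_STATUSES = ("CR", "EN", "VU")

SPECIES_COLUMNS = ["species_id", "taxon_class", "iucn_status", "lower_m", "upper_m"]
COVARIATE_COLUMNS = ["band_label", "area", "population_density"]
BAND_TABLE_COLUMNS = [
    "band_label",
    "richness",
    "mean_range_size",
    "area",
    "population_density",
    "null_mean",
    "null_lo",
    "null_hi",
]


class ValidationError(ValueError):
    """A located, typed error for a record that fails validation."""


class ConfigError(ValueError):
    """Invalid run configuration (missing files, inconsistent settings)."""


@dataclass(frozen=True)
class ElevationGrid:
    """The banded elevational domain plus augmentation clamp bounds.

    Parameters
    ----------
    domain_min, domain_max
        Hard boundaries of the gradient in meters; the domain length must be
        an exact multiple of ``band_width``.
    band_width
        Vertical extent of one band (m).
    clamp_min, clamp_max
        Hard bounds applied to augmented range limits.  ``clamp_min`` may sit
        above ``domain_min`` (the default 67 m reflects that the lowest
        terrain is slightly above the nominal domain floor).
    gradient_length_for_pct
        Gradient length used to convert augmentation percentages to meters
        (5000 m by default, so 20% -> 1000 m).
    """

    domain_min: int = 0
    domain_max: int = 4900
    band_width: int = 100
    clamp_min: int = 67
    clamp_max: int = 4900
    gradient_length_for_pct: int = 5000

    def __post_init__(self) -> None:
        if self.band_width <= 0:
            raise ValidationError("band_width must be positive")
        length = self.domain_max - self.domain_min
        if length <= 0 or length % self.band_width != 0:
            raise ValidationError(
                f"domain length {length} is not a positive multiple of "
                f"band_width {self.band_width}"
            )
        if not (self.domain_min <= self.clamp_min < self.clamp_max <= self.domain_max):
            raise ValidationError(
                "clamp bounds must satisfy domain_min <= clamp_min < clamp_max <= domain_max"
            )

    @property
    def n_bands(self) -> int:
        return (self.domain_max - self.domain_min) // self.band_width

    @property
    def band_labels(self) -> np.ndarray:
        """Upper edges of all bands, ascending."""
        return np.arange(
            self.domain_min + self.band_width,
            self.domain_max + self.band_width,
            self.band_width,
        )

    @property
    def domain_length(self) -> int:
        return self.domain_max - self.domain_min

    def band_of(self, elevation: float) -> int:
        """Label of the band containing ``elevation`` (band = (label-w, label])."""
        if not (self.domain_min <= elevation <= self.domain_max):
            raise ValidationError(f"elevation {elevation} outside domain")
        w = self.band_width
        label = int(math.ceil((elevation - self.domain_min) / w)) * w + self.domain_min
        return max(label, self.domain_min + w)


@dataclass(frozen=True)
class SpeciesRange:
    """One species' elevational occupancy interval, with taxon and threat status."""

    species_id: str
    taxon_class: str
    iucn_status: str
    lower_m: int
    upper_m: int

    def validate(self, grid: ElevationGrid) -> "SpeciesRange":
        if self.taxon_class not in TAXON_CLASSES:
            raise ValidationError(
                f"species {self.species_id!r}: unknown taxon_class {self.taxon_class!r}"
            )
        if self.iucn_status not in IUCN_STATUSES:
            raise ValidationError(
                f"species {self.species_id!r}: iucn_status must be one of "
                f"{IUCN_STATUSES}, got {self.iucn_status!r}"
            )
        if self.lower_m > self.upper_m:
            raise ValidationError(
                f"species {self.species_id!r}: lower_m {self.lower_m} > upper_m {self.upper_m}"
            )
        for name, v in (("lower_m", self.lower_m), ("upper_m", self.upper_m)):
            if not (grid.domain_min <= v <= grid.domain_max):
                raise ValidationError(
                    f"species {self.species_id!r}: {name}={v} outside domain "
                    f"[{grid.domain_min}, {grid.domain_max}]"
                )
        return self

    @property
    def range_size_m(self) -> int:
        return self.upper_m - self.lower_m


def _coerce_elevation(value, *, species_id: str, column: str, line: int) -> int | None:
    """Parse one elevation cell; None for missing, ValidationError if malformed."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str):
        value = value.strip()
        if value == "" or value.lower() in {"na", "nan", "none"}:
            return None
        try:
            value = float(value)
        except ValueError:
            raise ValidationError(
                f"line {line}: species {species_id!r}: {column}={value!r} is not numeric"
            ) from None
    f = float(value)
    if not math.isfinite(f):
        return None
    r = round(f)
    if r != f:
        logger.warning(
            "line %d: species %r: %s=%s rounded to %d m", line, species_id, column, f, r
        )
    return int(r)


def read_species_table(path, grid: ElevationGrid) -> list[SpeciesRange]:
    """Read and validate a species CSV (``species_id,taxon_class,iucn_status,lower_m,upper_m``).

    Rows with missing/undetermined elevational limits are rejected and logged
    (mirroring the exclusion of species without well-defined ranges from the
    analysis); structurally invalid rows raise :class:`ValidationError` naming
    the line and species.
    """
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    missing = [c for c in SPECIES_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    out: list[SpeciesRange] = []
    if df.empty:
        logger.warning("%s: no species rows (header only)", path)
        return out
    for i, row in df.iterrows():
        line = i + 2  # 1-based, after header
        sid = str(row["species_id"]).strip()
        lower = _coerce_elevation(row["lower_m"], species_id=sid, column="lower_m", line=line)
        upper = _coerce_elevation(row["upper_m"], species_id=sid, column="upper_m", line=line)
        if lower is None or upper is None:
            logger.warning(
                "line %d: species %r rejected: undetermined elevational range", line, sid
            )
            continue
        taxon = str(row["taxon_class"]).strip()
        if taxon not in TAXON_CLASSES:
            logger.warning("line %d: species %r: taxon_class %r mapped to 'other'",
                           line, sid, taxon)
            taxon = "other"
        sp = SpeciesRange(sid, taxon, str(row["iucn_status"]).strip(), lower, upper)
        try:
            sp.validate(grid)
        except ValidationError as e:
            raise ValidationError(f"line {line}: {e}") from None
        out.append(sp)
    return out


def write_species_table(species: list[SpeciesRange], path) -> None:
    pd.DataFrame(
        [
            {
                "species_id": s.species_id,
                "taxon_class": s.taxon_class,
                "iucn_status": s.iucn_status,
                "lower_m": s.lower_m,
                "upper_m": s.upper_m,
            }
            for s in species
        ],
        columns=SPECIES_COLUMNS,
    ).to_csv(path, index=False)


def read_band_covariates(path, grid: ElevationGrid) -> pd.DataFrame:
    """Read per-band covariates (``band_label,area,population_density``) aligned to the grid."""
    df = pd.read_csv(path)
    missing = [c for c in COVARIATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    df = df[COVARIATE_COLUMNS].copy()
    labels = df["band_label"].to_numpy()
    if not np.array_equal(np.sort(labels), grid.band_labels):
        raise ValidationError(
            f"{path}: band labels do not match the grid "
            f"({grid.n_bands} bands expected)"
        )
    if (df["area"] <= 0).any() or (df["population_density"] < 0).any():
        raise ValidationError(f"{path}: area must be positive and density non-negative")
    return df.sort_values("band_label").reset_index(drop=True)


def validate_band_table(table: pd.DataFrame, grid: ElevationGrid | None = None) -> pd.DataFrame:
    """Validate a band table (one row per band, labels strictly increasing)."""
    missing = [c for c in BAND_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"band table missing columns {missing}")
    labels = table["band_label"].to_numpy()
    if len(labels) != len(np.unique(labels)):
        raise ValidationError("band table has duplicated band_label values")
    diffs = np.diff(labels)
    if len(diffs) and not np.all(diffs == diffs[0]):
        raise ValidationError("band labels are not evenly spaced")
    if grid is not None and not np.array_equal(labels, grid.band_labels):
        raise ValidationError("band labels do not match the grid")
    rich = table["richness"].to_numpy()
    if np.any(rich < 0) or not np.allclose(rich, np.round(rich)):
        raise ValidationError("richness must be non-negative integers")
    mrs = table["mean_range_size"].to_numpy(dtype=float)
    bw = int(diffs[0]) if len(diffs) else (grid.band_width if grid else 0)
    bad = np.isfinite(mrs) & (mrs < bw)
    if bad.any():
        raise ValidationError(
            f"mean_range_size below band width at bands {labels[bad].tolist()}"
        )
    return table


def write_band_table(table: pd.DataFrame, path, grid: ElevationGrid | None = None) -> None:
    """Write a validated band table; missing values persist as empty fields."""
    validate_band_table(table, grid)
    table.to_csv(path, index=False, columns=BAND_TABLE_COLUMNS)


def read_band_table(path, grid: ElevationGrid | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["richness"] = df["richness"].astype(int)
    return validate_band_table(df, grid)
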