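"""Core domain types shared by every stage of the pipeline.

Conventions fixed here:

* ``band_radii`` includes the birth band as its first entry, ordered from
  the focus outward, in mm.
* ``band_count`` (reported everywhere else) counts translucent bands
  *beyond* the birth band, i.e. ``len(band_radii) - 1``.
* Lengths are total length (TL) in cm; radii are mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

SEXES = ("female", "male")
EDGE_TYPES = ("opaque", "translucent", "unknown")


class ValidationError(ValueError):
    """A record violated a domain invariant."""


@dataclass(frozen=True)
class SpecimenRecord:
    """One aged individual: morphometrics plus vertebral measurements."""

    specimen_id: str
    sex: str
    total_length: float          # cm TL
    capture_year: int
    capture_month: int           # 1-12
    vertebral_radius: float      # mm, focus to edge along the corpus calcareum
    band_radii: tuple[float, ...]  # mm, birth band first, strictly increasing
    edge_type: str = "unknown"

    def __post_init__(self) -> None:
        object.__setattr__(self, "band_radii", tuple(float(r) for r in self.band_radii))
        sid = self.specimen_id
        if self.sex not in SEXES:
            raise ValidationError(f"{sid}: sex must be one of {SEXES}, got {self.sex!r}")
        if self.edge_type not in EDGE_TYPES:
            raise ValidationError(
                f"{sid}: edge_type must be one of {EDGE_TYPES}, got {self.edge_type!r}"
            )
        if not self.total_length > 0:
            raise ValidationError(f"{sid}: total_length must be > 0")
        if not self.vertebral_radius > 0:
            raise ValidationError(f"{sid}: vertebral_radius must be > 0")
        if not 1 <= self.capture_month <= 12:
            raise ValidationError(f"{sid}: capture_month must be in 1..12")
        radii = self.band_radii
        if any(b <= a for a, b in zip(radii, radii[1:])):
            raise ValidationError(f"{sid}: band_radii must be strictly increasing: {radii}")
        if radii and radii[-1] > self.vertebral_radius:
            raise ValidationError(
                f"{sid}: last band radius {radii[-1]} exceeds vertebral radius "
                f"{self.vertebral_radius}"
            )

    @property
    def band_count(self) -> int:
        """Number of post-birth translucent bands (birth band excluded)."""
        return max(len(self.band_radii) - 1, 0)


@dataclass(frozen=True)
class ReaderCountRecord:
    """A single band count made by one reader on one specimen."""

    specimen_id: str
    reader_id: int
    trial: int
    band_count: int

    def __post_init__(self) -> None:
        if self.band_count < 0:
            raise ValidationError(f"{self.specimen_id}: band_count must be >= 0")
        if self.trial < 1:
            raise ValidationError(f"{self.specimen_id}: trial must be >= 1")


@dataclass
class AgeLengthTable:
    """Counts of individuals (or records) on a 2-cm length x integer age grid.

    Stored long-form: one row per non-empty (length_bin_lower, age_group)
    cell. Age groups are down-rounded decimal ages.
    """

    data: pd.DataFrame
    bin_width: float = 2.0

    def __post_init__(self) -> None:
        required = {"length_bin_lower", "age_group", "count"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"AgeLengthTable missing columns: {sorted(missing)}")
        if (self.data["count"] < 0).any():
            raise ValidationError("AgeLengthTable counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.data["count"].sum())

    def age_marginal(self) -> pd.Series:
        """Counts per age group, ascending."""
        return self.data.groupby("age_group")["count"].sum().sort_index()

    def length_marginal(self) -> pd.Series:
        """Counts per length-bin lower edge, ascending."""
        return self.data.groupby("length_bin_lower")["count"].sum().sort_index()

    def bin_midpoint(self, lower: float) -> float:
        return lower + self.bin_width / 2.0


def specimens_to_frame(specimens: Sequence[SpecimenRecord]) -> pd.DataFrame:
    """Flatten specimen records to a DataFrame (band_radii ';'-joined)."""
    return pd.DataFrame(
        {
            "specimen_id": [s.specimen_id for s in specimens],
            "sex": [s.sex for s in specimens],
            "total_length": [s.total_length for s in specimens],
            "capture_year": [s.capture_year for s in specimens],
            "capture_month": [s.capture_month for s in specimens],
            "vertebral_radius": [s.vertebral_radius for s in specimens],
            "band_radii": [";".join(repr(r) for r in s.band_radii) for s in specimens],
            "edge_type": [s.edge_type for s in specimens],
        }
    )
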