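"""Decimal age assignment from band counts.

Three schemes:

* ``unadjusted``     — age equals the post-birth band count (each band one
  completed year).
* ``adjusted_rc``    — accounts for the offset between the birth pulse and
  the first band: age = offset + (count - 1), offset exactly 7/12 yr by
  default (births peak in August, bands complete in April).
* ``adjusted_dc``    — additionally adds the time elapsed between band
  formation and capture: + ((capture_month - formation_month) mod 12)/12.

The 7/12 offset is stored exactly; rounding to 0.58 is display-only so
downstream likelihoods are not quantized.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

SCHEME_NAMES = ("unadjusted", "adjusted_rc", "adjusted_dc")

#: Exact default offset between birth and first band formation (7 months).
DEFAULT_BIRTH_OFFSET = Fraction(7, 12)


@dataclass(frozen=True)
class AgeScheme:
    name: str
    birth_month: int = 8
    band_formation_month: int = 4
    birth_offset_years: float = float(DEFAULT_BIRTH_OFFSET)

    def __post_init__(self) -> None:
        if self.name not in SCHEME_NAMES:
            raise ValueError(f"scheme name must be one of {SCHEME_NAMES}")
        if not 0 < self.birth_offset_years < 1:
            raise ValueError("birth_offset_years must be in (0, 1)")
        for m in (self.birth_month, self.band_formation_month):
            if not 1 <= m <= 12:
                raise ValueError("months must be in 1..12")

    @classmethod
    def unadjusted(cls) -> "AgeScheme":
        return cls("unadjusted")

    @classmethod
    def adjusted_rc(cls) -> "AgeScheme":
        return cls("adjusted_rc")

    @classmethod
    def adjusted_dc(cls) -> "AgeScheme":
        return cls("adjusted_dc")

    @classmethod
    def from_name(cls, name: str) -> "AgeScheme":
        return cls(name)


@dataclass(frozen=True)
class AgeAssignment:
    specimen_id: str
    scheme: str
    decimal_age: float
    age_group: int  # floor(decimal_age), the down-rounded tabulation age


def months_since_formation(capture_month: int, scheme: AgeScheme) -> int:
    """Whole months elapsed since the most recent band-formation month,
    wrapping across the new year (Jan-Mar captures count 9-11 months)."""
    return (capture_month - scheme.band_formation_month) % 12


def assign_age(
    band_count: int,
    capture_month: int,
    scheme: AgeScheme,
    specimen_id: str = "",
) -> AgeAssignment:
    """Decimal age of a captured fish from its post-birth band count."""
    if band_count < 0:
        raise ValueError("band_count must be >= 0")
    if not 1 <= capture_month <= 12:
        raise ValueError("capture_month must be in 1..12")
    if band_count == 0:
        if scheme.name != "unadjusted":
            raise ValueError(
                "band_count=0 (neonate) is only meaningful under the unadjusted scheme"
            )
        age = 0.0
    elif scheme.name == "unadjusted":
        age = float(band_count)
    elif scheme.name == "adjusted_rc":
        age = scheme.birth_offset_years + (band_count - 1)
    else:  # adjusted_dc
        age = (
            scheme.birth_offset_years
            + (band_count - 1)
            + months_since_formation(capture_month, scheme) / 12.0
        )
    return AgeAssignment(specimen_id, scheme.name, age, int(age // 1))


def age_for_band(band_index: int, scheme: AgeScheme) -> float:
    """Age at which the band with this index was deposited.

    Band 0 is the birth band (age 0). Band i >= 1 is the i-th post-birth
    band: age i unadjusted, offset + (i - 1) under either adjustment (the
    capture-date term does not apply to past depositions).
    """
    if band_index < 0:
        raise ValueError("band_index must be >= 0")
    if band_index == 0:
        return 0.0
    if scheme.name == "unadjusted":
        return float(band_index)
    return scheme.birth_offset_years + (band_index - 1)
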