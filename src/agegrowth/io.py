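"""CSV readers/writers and packaged reference tables.

The CSV dialect is fixed: UTF-8, comma-separated, '.' decimal separator.
``band_radii`` is serialized as a ';'-joined list so a specimen stays on
one row.
"""

from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .types import (
    AgeLengthTable,
    ReaderCountRecord,
    SpecimenRecord,
    ValidationError,
    specimens_to_frame,
)

SPECIMEN_COLUMNS = [
    "specimen_id",
    "sex",
    "total_length",
    "capture_year",
    "capture_month",
    "vertebral_radius",
    "band_radii",
    "edge_type",
]
READER_COLUMNS = ["specimen_id", "reader_id", "trial", "band_count"]

#: Printed grand totals asserted every time a fixture is loaded.
FIXTURE_TOTALS = {"table1": 245, "table2": 245, "table3": 1893}

_FIXTURE_FILES = {
    "table1": "table1_monthly_n.csv",
    "table2": "table2_observed_age_length.csv",
    "table3": "table3_combined_age_length.csv",
    "table4": "table4_growth_fits.csv",
}


class FormatError(ValueError):
    """Input file does not match the documented layout."""


def _parse_band_radii(raw: str) -> tuple[float, ...]:
    raw = raw.strip()
    if not raw:
        return ()
    return tuple(float(tok) for tok in raw.split(";"))


def load_specimens(path: str | Path) -> list[SpecimenRecord]:
    """Read a specimen CSV, validating every row.

    Raises :class:`FormatError` when columns are missing and
    :class:`~agegrowth.types.ValidationError` (with the row index and
    specimen id) for the first row violating a domain invariant.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in SPECIMEN_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"{path}: missing column(s) {missing}")
        records = []
        for i, row in enumerate(reader):
            try:
                records.append(
                    SpecimenRecord(
                        specimen_id=row["specimen_id"],
                        sex=row["sex"],
                        total_length=float(row["total_length"]),
                        capture_year=int(row["capture_year"]),
                        capture_month=int(row["capture_month"]),
                        vertebral_radius=float(row["vertebral_radius"]),
                        band_radii=_parse_band_radii(row["band_radii"]),
                        edge_type=row["edge_type"] or "unknown",
                    )
                )
            except (ValidationError, ValueError) as exc:
                raise ValidationError(f"row {i + 2}: {exc}") from exc
    return records


def save_specimens(specimens: Sequence[SpecimenRecord], path: str | Path) -> None:
    specimens_to_frame(specimens).to_csv(path, index=False)


def load_reader_counts(path: str | Path) -> list[ReaderCountRecord]:
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in READER_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    return [
        ReaderCountRecord(
            specimen_id=str(row.specimen_id),
            reader_id=int(row.reader_id),
            trial=int(row.trial),
            band_count=int(row.band_count),
        )
        for row in frame.itertuples()
    ]


def save_reader_counts(records: Iterable[ReaderCountRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(r.specimen_id, r.reader_id, r.trial, r.band_count) for r in records],
        columns=READER_COLUMNS,
    ).to_csv(path, index=False)


def _fixture_frame(name: str) -> pd.DataFrame:
    source = resources.files("agegrowth.fixtures") / _FIXTURE_FILES[name]
    with resources.as_file(source) as fp:
        return pd.read_csv(fp)


def load_fixture(name: str):
    """Return a packaged reference table.

    ``table1`` -> Series of monthly sample sizes indexed by month (1-12);
    ``table2``/``table3`` -> :class:`AgeLengthTable`;
    ``table4`` -> DataFrame of reference growth-model fits.
    Grand totals are asserted on every load.
    """
    if name not in _FIXTURE_FILES:
        raise KeyError(f"unknown fixture {name!r}; expected one of {sorted(_FIXTURE_FILES)}")
    frame = _fixture_frame(name)
    if name == "table1":
        series = frame.set_index("month")["count"]
        if int(series.sum()) != FIXTURE_TOTALS["table1"]:
            raise ValidationError("table1 monthly counts do not sum to the readable total")
        return series
    if name in ("table2", "table3"):
        table = AgeLengthTable(frame)
        if table.total != FIXTURE_TOTALS[name]:
            raise ValidationError(
                f"{name} total {table.total} != printed {FIXTURE_TOTALS[name]}"
            )
        return table
    return frame
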