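"""CSV input/output for cross-sectional morphometric tables.

The on-disk schema is a comma-separated UTF-8 table with header columns
``animal_id, sex, age_value, age_unit, measure, value_mm``.  Sex codes are
``M``/``F``/``I`` (indifferent); ``age_unit`` is ``days`` or ``months`` and
is an explicit column — never inferred from magnitude.  Ages are normalised
to 28-day months on read.  Malformed rows are dropped with a logged reason,
never silently, and the parse report reconciles: read = kept + dropped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .records import MorphRecord, records_to_frame
from .sj2p import DAYS_PER_MONTH

__all__ = ["FormatError", "Dataset", "read_morph_csv", "write_morph_csv"]

logger = logging.getLogger("growthseam")

_REQUIRED = ["animal_id", "sex", "age_value", "age_unit", "measure", "value_mm"]
_SEX_CODES = {"M": "male", "F": "female", "I": "indifferent"}
_AGE_UNITS = {"days", "months"}
_MEASURES = {"pes", "head", "tail"}


class FormatError(ValueError):
    """The input file does not conform to the expected schema."""


@dataclass
class Dataset:
    """Parsed records plus their provenance (what was read, kept, dropped)."""

    records: list[MorphRecord]
    source: str = ""
    rows_read: int = 0
    dropped: list[tuple[int, str]] = field(default_factory=list)  # (row index, reason)

    def __post_init__(self):
        assert self.rows_read == len(self.records) + len(self.dropped), \
            "provenance does not reconcile"

    def provenance(self) -> dict:
        return {
            "source": self.source,
            "rows_read": self.rows_read,
            "rows_kept": len(self.records),
            "rows_dropped": len(self.dropped),
            "drop_reasons": [{"row": i, "reason": r} for i, r in self.dropped],
        }


def _parse_row(i: int, row) -> MorphRecord:
    sex_code = str(row.sex).strip()
    if sex_code not in _SEX_CODES:
        raise ValueError(f"unknown sex code {sex_code!r}")
    unit = str(row.age_unit).strip().lower()
    age_raw = row.age_value
    if pd.isna(age_raw) or str(age_raw).strip() == "":
        age_months = None
    else:
        age = float(age_raw)
        if unit not in _AGE_UNITS:
            raise ValueError(f"unknown age unit {unit!r}")
        if age < 0 or not math.isfinite(age):
            raise ValueError(f"invalid age {age}")
        age_months = age / DAYS_PER_MONTH if unit == "days" else age
    measure = str(row.measure).strip().lower()
    if measure not in _MEASURES:
        raise ValueError(f"unknown measure {measure!r}")
    value = float(row.value_mm)
    if not (math.isfinite(value) and value > 0):
        raise ValueError("non-positive measurement")
    return MorphRecord(
        animal_id=str(row.animal_id),
        sex=_SEX_CODES[sex_code],
        age_months=age_months,
        measure=measure,
        value_mm=value,
    )


def read_morph_csv(path: str) -> Dataset:
    """Read a morphometric CSV, normalising ages to 28-day months.

    Raises :class:`FormatError` for a missing file/header column or when no
    valid rows remain; individual malformed rows are dropped and reported.
    """
    try:
        df = pd.read_csv(path, dtype={"animal_id": str})
    except FileNotFoundError:
        raise
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as e:
        raise FormatError(f"cannot parse {path}: {e}") from e
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")

    records: list[MorphRecord] = []
    dropped: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            records.append(_parse_row(i, row))
        except (ValueError, TypeError) as e:
            reason = str(e)
            dropped.append((i, reason))
            logger.info("dropped row %d of %s: %s", i, path, reason)
    if not records:
        raise FormatError(f"{path} contains no valid rows "
                          f"({len(dropped)} dropped)")
    return Dataset(records=records, source=str(path), rows_read=len(df),
                   dropped=dropped)


def write_morph_csv(records: list[MorphRecord], path: str) -> None:
    """Write records in the standard schema (ages in months)."""
    df = records_to_frame(records)
    out = pd.DataFrame(
        {
            "animal_id": df["animal_id"],
            "sex": df["sex"].map({v: k for k, v in _SEX_CODES.items()}),
            "age_value": df["age_months"],
            "age_unit": "months",
            "measure": df["measure"],
            "value_mm": df["value_mm"],
        }
    )
    out.to_csv(path, index=False)
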