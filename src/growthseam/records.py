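"""The in-memory unit of cross-sectional morphometric data."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["MorphRecord", "records_to_frame", "frame_to_records", "known_age_arrays"]

_SEXES = {"male", "female", "indifferent"}
_MEASURES = {"pes", "head", "tail"}


@dataclass(frozen=True)
class MorphRecord:
    """One animal: sex, age in months (if known), measurement type and value (mm)."""

    animal_id: str
    sex: str
    age_months: Optional[float]
    measure: str
    value_mm: float

    def __post_init__(self):
        if self.sex not in _SEXES:
            raise ValueError(f"sex must be one of {sorted(_SEXES)}, got {self.sex!r}")
        if self.measure not in _MEASURES:
            raise ValueError(
                f"measure must be one of {sorted(_MEASURES)}, got {self.measure!r}"
            )
        if not self.value_mm > 0:
            raise ValueError(f"measurement must be positive, got {self.value_mm}")
        if self.age_months is not None and self.age_months < 0:
            raise ValueError(f"age must be >= 0, got {self.age_months}")


def records_to_frame(records: list[MorphRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "animal_id": [r.animal_id for r in records],
            "sex": [r.sex for r in records],
            "age_months": [r.age_months for r in records],
            "measure": [r.measure for r in records],
            "value_mm": [r.value_mm for r in records],
        }
    )


def frame_to_records(df: pd.DataFrame) -> list[MorphRecord]:
    return [
        MorphRecord(
            animal_id=str(row.animal_id),
            sex=str(row.sex),
            age_months=None if pd.isna(row.age_months) else float(row.age_months),
            measure=str(row.measure),
            value_mm=float(row.value_mm),
        )
        for row in df.itertuples(index=False)
    ]


def known_age_arrays(records: list[MorphRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Ages (months) and values (mm) of the records with known age, data order."""
    pairs = [(r.age_months, r.value_mm) for r in records if r.age_months is not None]
    if not pairs:
        return np.empty(0), np.empty(0)
    ages, values = zip(*pairs)
    return np.asarray(ages, dtype=float), np.asarray(values, dtype=float)
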