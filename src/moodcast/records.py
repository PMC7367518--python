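"""In-memory containers for daily self-assessment data.

The canonical container is a long-format :class:`pandas.DataFrame` with one
row per patient-day (columns ``patient_id``, ``date`` and the ten
questionnaire items).  :class:`PatientSeries` wraps one patient's
date-ordered slice and is the unit of cross-validation partitioning.
Missing days are absent rows — they are never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as Date

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .items import (
    CSV_COLUMNS,
    ITEM_COLUMNS,
    ITEM_RANGES,
    MEDICINE_CATEGORIES,
    is_valid_mood,
)


@dataclass(frozen=True)
class SelfAssessmentRecord:
    """One patient-day of raw questionnaire answers."""

    patient_id: str
    date: Date
    activity: int
    alcohol: int
    anxiety: int
    irritable: int
    cognitive_difficulty: int
    medicine: str
    mixed_mood: int
    mood: float
    sleep: float
    stress: int


@dataclass
class PatientSeries:
    """Date-ordered records for one patient.

    ``data`` holds one row per observed day with strictly increasing dates;
    gaps are allowed and meaningful (a missing day was simply not reported).
    """

    patient_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in ["date"] + ITEM_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"patient {self.patient_id}: missing columns {missing}")
        dates = pd.to_datetime(df["date"])
        if not dates.is_monotonic_increasing or dates.duplicated().any():
            raise ValidationError(
                f"patient {self.patient_id}: dates must be strictly increasing and unique"
            )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def dates(self) -> pd.Series:
        return pd.to_datetime(self.data["date"])

    @property
    def first_date(self) -> pd.Timestamp:
        return self.dates.iloc[0]

    @property
    def records(self) -> list[SelfAssessmentRecord]:
        out = []
        for row in self.data.itertuples(index=False):
            out.append(
                SelfAssessmentRecord(
                    patient_id=self.patient_id,
                    date=pd.Timestamp(row.date).date(),
                    activity=int(row.activity),
                    alcohol=int(row.alcohol),
                    anxiety=int(row.anxiety),
                    irritable=int(row.irritable),
                    cognitive_difficulty=int(row.cognitive_difficulty),
                    medicine=str(row.medicine),
                    mixed_mood=int(row.mixed_mood),
                    mood=float(row.mood),
                    sleep=float(row.sleep),
                    stress=int(row.stress),
                )
            )
        return out


def validate_frame(df: pd.DataFrame) -> None:
    """Validate a long-format dataset against the questionnaire schema.

    Checks column presence, item ranges, the 9-level mood scale, the
    medicine categories and (patient_id, date) uniqueness.
    """
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing columns {missing}")
    if df.duplicated(subset=["patient_id", "date"]).any():
        raise ValidationError("(patient_id, date) pairs must be unique")
    bad_med = set(df["medicine"].unique()) - set(MEDICINE_CATEGORIES)
    if bad_med:
        raise ValidationError(f"unknown medicine categories: {sorted(bad_med)}")
    for item, (lo, hi) in ITEM_RANGES.items():
        vals = pd.to_numeric(df[item])
        if ((vals < lo) | (vals > hi)).any():
            raise ValidationError(f"item {item!r} outside allowed range [{lo}, {hi}]")
    if not np.all(is_valid_mood(df["mood"].to_numpy())):
        raise ValidationError("mood values must sit exactly on the 9-level scale")


def frame_to_series(df: pd.DataFrame, validate: bool = True) -> list[PatientSeries]:
    """Split a long-format dataset into per-patient series (sorted by id)."""
    if len(df) == 0:
        raise ValidationError("empty dataset")
    if validate:
        validate_frame(df)
    out = []
    for pid, grp in df.groupby("patient_id", sort=True):
        grp = grp.drop(columns="patient_id").sort_values("date").reset_index(drop=True)
        out.append(PatientSeries(patient_id=str(pid), data=grp))
    return out


def series_to_frame(series: list[PatientSeries]) -> pd.DataFrame:
    """Concatenate per-patient series back into one long-format dataset."""
    if not series:
        raise ValidationError("empty series collection")
    frames = []
    for s in series:
        df = s.data.copy()
        df.insert(0, "patient_id", s.patient_id)
        frames.append(df[CSV_COLUMNS])
    return pd.concat(frames, ignore_index=True)
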