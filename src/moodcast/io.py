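"""CSV dialect for self-assessment datasets.

One row per patient-day; header is ``patient_id,date`` followed by the ten
questionnaire item names; dates are ISO-8601; UTF-8; ``.`` decimal.  The
writer uses fixed numeric formatting so identical data produce
byte-identical files.
"""

from __future__ import annotations

import os

import pandas as pd

from .items import CSV_COLUMNS
from .records import PatientSeries, frame_to_series, series_to_frame

_INT_ITEMS = [
    "activity",
    "alcohol",
    "anxiety",
    "irritable",
    "cognitive_difficulty",
    "mixed_mood",
    "stress",
]


def write_csv(series: list[PatientSeries], path: str | os.PathLike) -> None:
    """Write patient series to the long-format CSV dialect."""
    df = series_to_frame(series).copy()
    df["date"] = pd.to_datetime(df["date"]).dt.strftime("%Y-%m-%d")
    for col in _INT_ITEMS:
        df[col] = df[col].astype(int)
    # mood and sleep carry halves; one decimal is exact for both
    df["mood"] = df["mood"].map(lambda v: f"{v:.1f}")
    df["sleep"] = df["sleep"].map(lambda v: f"{v:.1f}")
    df[CSV_COLUMNS].to_csv(path, index=False)


def read_csv(path: str | os.PathLike, validate: bool = True) -> list[PatientSeries]:
    """Read the long-format CSV dialect back into validated patient series."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    df["date"] = pd.to_datetime(df["date"])
    return frame_to_series(df, validate=validate)
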