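"""Raw records -> model-ready windowed design matrices.

Three item-level transforms precede windowing:

* ``medicine`` (categorical) becomes two exclusive binaries,
  ``medicine_omitted`` and ``medicine_changed``.
* ``sleep`` is centered on the patient's own mean and split into a
  non-positive and a non-negative deviation component, so shortened and
  lengthened sleep can carry different weights.
* every predictor is min-max normalised to [0, 1] by its allowed range
  (the split sleep components by a fixed +/-12 h range, keeping the
  transform data-independent).

A forecast example then stacks ``w`` consecutive fully-observed days of the
12 predictors (oldest day first) and targets the raw mood ``h`` days after
the window's newest day (the anchor).  Windows never span missing days and
nothing is imputed; the target stays on the raw -3..3 scale.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError
from .items import N_PREDICTORS, PREDICTOR_RANGES, PREDICTORS
from .records import PatientSeries

__all__ = [
    "encode_medicine",
    "split_sleep",
    "normalize_items",
    "build_windows",
    "feature_labels",
    "ForecastExample",
    "ForecastDataset",
]

_MEDICINE_CODES = {
    "taken": (0, 0),
    "not_taken": (1, 0),
    "taken_with_changes": (0, 1),
}


def encode_medicine(raw: str) -> tuple[int, int]:
    """Encode the categorical medicine item as two exclusive binaries
    ``(medicine_omitted, medicine_changed)``."""
    try:
        return _MEDICINE_CODES[raw]
    except KeyError:
        raise ValidationError(f"unknown medicine category: {raw!r}") from None


def split_sleep(series: PatientSeries, mean: float | None = None) -> pd.DataFrame:
    """Split sleep into deviation components around the patient's mean.

    Returns a frame with columns ``sleep_negative`` (= min(d, 0)) and
    ``sleep_positive`` (= max(d, 0)) where d = sleep - patient mean, in raw
    hours; the two always sum back to d.  ``mean`` overrides the patient
    mean (e.g. a training-period mean).
    """
    sleep = pd.to_numeric(series.data["sleep"], errors="coerce")
    observed = sleep.dropna()
    if len(observed) == 0:
        raise ValidationError(f"patient {series.patient_id}: no sleep observations")
    m = float(observed.mean()) if mean is None else float(mean)
    d = sleep - m
    return pd.DataFrame(
        {"sleep_negative": np.minimum(d, 0.0), "sleep_positive": np.maximum(d, 0.0)},
        index=series.data.index,
    )


def normalize_items(values: Mapping[str, float] | pd.DataFrame):
    """Min-max normalise predictor values to [0, 1] by their allowed range.

    Accepts a mapping (returned as a dict) or a DataFrame of predictor
    columns.  Out-of-range values raise; binary items pass through
    unchanged because their range is already {0, 1}.
    """
    if isinstance(values, pd.DataFrame):
        out = values.copy()
        for col in values.columns:
            out[col] = _normalize_one(col, values[col].to_numpy(dtype=float))
        return out
    return {k: float(_normalize_one(k, np.asarray(v, dtype=float))) for k, v in values.items()}


def _normalize_one(name: str, arr: np.ndarray) -> np.ndarray:
    if name not in PREDICTOR_RANGES:
        raise ValidationError(f"unknown predictor: {name!r}")
    lo, hi = PREDICTOR_RANGES[name]
    if np.any(arr < lo) or np.any(arr > hi):
        raise ValidationError(f"predictor {name!r} outside allowed range [{lo}, {hi}]")
    return (arr - lo) / (hi - lo)


def feature_labels(w: int) -> list[str]:
    """Flattened feature names, oldest day first: ``item@lag`` with lag
    counted in days before the anchor (newest day is lag 0)."""
    return [f"{item}@{lag}" for lag in range(w - 1, -1, -1) for item in PREDICTORS]


@dataclass(frozen=True)
class ForecastExample:
    """One windowed training/test example for one patient."""

    patient_index: int
    anchor_date: pd.Timestamp
    features: np.ndarray  # shape (w, 12), preprocessed, oldest day first
    target: float  # raw mood at anchor + h days


@dataclass
class ForecastDataset:
    """Windowed design matrix for one (w, h) configuration.

    ``X`` has one row per example (12*w columns in ``feature_names``
    order), ``y`` the raw mood target, ``patient_index`` positions into
    ``patient_ids``.  ``patient_first_date`` (first observed day per
    patient) anchors the cross-validation partitioning.
    """

    X: np.ndarray
    y: np.ndarray
    patient_index: np.ndarray
    anchor_dates: np.ndarray  # datetime64[D], per example
    patient_ids: list[str]
    w: int
    h: int
    feature_names: list[str] = field(default_factory=list)
    patient_first_date: dict[str, pd.Timestamp] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.feature_names:
            self.feature_names = feature_labels(self.w)
        if self.X.shape[1] != N_PREDICTORS * self.w:
            raise ValidationError("feature matrix width must be 12*w")
        if len(self.patient_index) and self.patient_index.max() >= len(self.patient_ids):
            raise ValidationError("patient_index out of range")

    @property
    def n_examples(self) -> int:
        return len(self.y)

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def target_dates(self) -> np.ndarray:
        return self.anchor_dates + np.timedelta64(self.h, "D")

    def examples(self) -> list[ForecastExample]:
        return [
            ForecastExample(
                patient_index=int(j),
                anchor_date=pd.Timestamp(a),
                features=x.reshape(self.w, N_PREDICTORS),
                target=float(t),
            )
            for j, a, x, t in zip(self.patient_index, self.anchor_dates, self.X, self.y)
        ]

    def subset(self, indices: np.ndarray) -> "ForecastDataset":
        """Row subset keeping the patient catalogue (indices stay stable)."""
        idx = np.asarray(indices)
        return ForecastDataset(
            X=self.X[idx],
            y=self.y[idx],
            patient_index=self.patient_index[idx],
            anchor_dates=self.anchor_dates[idx],
            patient_ids=list(self.patient_ids),
            w=self.w,
            h=self.h,
            feature_names=list(self.feature_names),
            patient_first_date=dict(self.patient_first_date),
        )


def _predictor_matrix(series: PatientSeries, sleep_mean: float | None) -> np.ndarray:
    """Per-record preprocessed predictors (n_records, 12) for one patient."""
    df = series.data
    med = np.array([encode_medicine(m) for m in df["medicine"]], dtype=float)
    sl = split_sleep(series, mean=sleep_mean)
    # deviations beyond the fixed +/-12 h normalisation range are clamped
    pred = pd.DataFrame(
        {
            "mood": df["mood"].to_numpy(dtype=float),
            "activity": df["activity"].to_numpy(dtype=float),
            "alcohol": df["alcohol"].to_numpy(dtype=float),
            "anxiety": df["anxiety"].to_numpy(dtype=float),
            "irritable": df["irritable"].to_numpy(dtype=float),
            "cognitive_difficulty": df["cognitive_difficulty"].to_numpy(dtype=float),
            "medicine_omitted": med[:, 0],
            "medicine_changed": med[:, 1],
            "mixed_mood": df["mixed_mood"].to_numpy(dtype=float),
            "sleep_negative": np.clip(sl["sleep_negative"].to_numpy(), -12.0, 0.0),
            "sleep_positive": np.clip(sl["sleep_positive"].to_numpy(), 0.0, 12.0),
            "stress": df["stress"].to_numpy(dtype=float),
        }
    )[PREDICTORS]
    return normalize_items(pred).to_numpy(dtype=float)


def build_windows(
    series: Sequence[PatientSeries],
    w: int,
    h: int,
    sleep_means: Mapping[str, float] | None = None,
) -> ForecastDataset:
    """Build the windowed design matrix for window size ``w`` and horizon ``h``.

    One example is emitted per (patient, anchor day t) with days
    t-w+1..t and the target day t+h all observed.  Patients contributing
    no example are dropped and do not count toward the patient catalogue.
    ``sleep_means`` optionally pins each patient's sleep-centering mean
    (e.g. to a training-period value).
    """
    if w < 1:
        raise ConfigurationError("window size w must be >= 1")
    if h < 1:
        raise ConfigurationError("horizon h must be >= 1")

    per_patient: list[tuple[PatientSeries, np.ndarray, np.ndarray, np.ndarray]] = []
    for s in series:
        pred = _predictor_matrix(s, sleep_means.get(s.patient_id) if sleep_means else None)
        days = (s.dates - s.first_date).dt.days.to_numpy()
        span = int(days[-1]) + 1
        row_of_day = np.full(span + h, -1, dtype=int)
        row_of_day[days] = np.arange(len(days))
        observed = row_of_day >= 0

        # anchor day t needs t-w+1..t observed and t+h observed
        ok = observed[: span].copy()
        for back in range(1, w):
            shifted = np.zeros(span, dtype=bool)
            shifted[back:] = observed[: span - back]
            ok &= shifted
        future = np.zeros(span, dtype=bool)
        future[: span - h] = observed[h:span]
        ok &= future
        anchors = np.nonzero(ok)[0]
        if len(anchors) == 0:
            continue

        feats = np.empty((len(anchors), w * N_PREDICTORS))
        for i, back in enumerate(range(w - 1, -1, -1)):
            feats[:, i * N_PREDICTORS : (i + 1) * N_PREDICTORS] = pred[row_of_day[anchors - back]]
        targets = s.data["mood"].to_numpy(dtype=float)[row_of_day[anchors + h]]
        anchor_dates = (s.first_date.to_datetime64() + anchors.astype("timedelta64[D]")).astype(
            "datetime64[D]"
        )
        per_patient.append((s, feats, targets, anchor_dates))

    patient_ids = [s.patient_id for s, *_ in per_patient]
    if per_patient:
        X = np.concatenate([f for _, f, _, _ in per_patient])
        y = np.concatenate([t for _, _, t, _ in per_patient])
        pidx = np.concatenate(
            [np.full(len(t), j, dtype=int) for j, (_, _, t, _) in enumerate(per_patient)]
        )
        dates = np.concatenate([d for _, _, _, d in per_patient])
    else:
        X = np.empty((0, w * N_PREDICTORS))
        y = np.empty(0)
        pidx = np.empty(0, dtype=int)
        dates = np.empty(0, dtype="datetime64[D]")
    return ForecastDataset(
        X=X,
        y=y,
        patient_index=pidx,
        anchor_dates=dates,
        patient_ids=patient_ids,
        w=w,
        h=h,
        patient_first_date={s.patient_id: s.first_date for s, *_ in per_patient},
    )


def write_windows_csv(dataset: ForecastDataset, path: str | os.PathLike) -> None:
    """Write one row per example (patient_id, anchor_date, features, target)
    plus a ``.json`` sidecar with (w, h, J, N, feature_names)."""
    df = pd.DataFrame(dataset.X, columns=dataset.feature_names)
    df.insert(0, "anchor_date", pd.to_datetime(dataset.anchor_dates).strftime("%Y-%m-%d"))
    df.insert(0, "patient_id", [dataset.patient_ids[j] for j in dataset.patient_index])
    df["target"] = dataset.y
    df.to_csv(path, index=False, float_format="%.10g")
    sidecar = {
        "w": dataset.w,
        "h": dataset.h,
        "J": dataset.n_patients,
        "N": dataset.n_examples,
        "feature_names": dataset.feature_names,
    }
    with open(str(path) + ".json", "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=2)
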