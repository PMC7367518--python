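"""Naive and standard machine-learning baseline forecasters.

The comparison suite the hierarchical models are judged against:

* ``last_observed`` — repeat the window's newest observed mood (a strong
  naive forecaster given mood's autocorrelation).
* ``pooled_mean`` / ``separate_mean`` — the training-target mean, global
  or per patient.
* ``pooled_ridge`` / ``separate_ridge`` — ridge regression on the
  flattened window features (lambda = 1 on the normalised features).
* ``pooled_gbt`` / ``separate_gbt`` — gradient-boosted trees
  (100 rounds, depth 3, learning rate 0.1).

``separate_*`` variants hold one sub-model per training patient and refuse
prediction for unseen patients (the cold-start failure the hierarchical
models avoid).  Hyperparameters are fixed and recorded on the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.linear_model import Ridge
from xgboost import XGBRegressor

from .exceptions import ColdStartError, ValidationError
from .items import PREDICTOR_RANGES
from .preprocessing import ForecastDataset

__all__ = ["BASELINE_KINDS", "BaselineModel", "fit_baseline"]

BASELINE_KINDS = (
    "last_observed",
    "pooled_mean",
    "separate_mean",
    "pooled_ridge",
    "separate_ridge",
    "pooled_gbt",
    "separate_gbt",
)

RIDGE_PARAMS = {"alpha": 1.0}
GBT_PARAMS = {
    "n_estimators": 100,
    "max_depth": 3,
    "learning_rate": 0.1,
    "n_jobs": 1,
    "random_state": 0,
    "verbosity": 0,
}


def _make_regressor(kind: str):
    if kind.endswith("ridge"):
        return Ridge(**RIDGE_PARAMS)
    return XGBRegressor(**GBT_PARAMS)


@dataclass
class BaselineModel:
    """A fitted baseline forecaster."""

    kind: str
    feature_names: list[str]
    state: dict[str, Any] = field(default_factory=dict)
    hyperparams: dict[str, Any] = field(default_factory=dict)

    def predict(self, data: ForecastDataset, allow_missing: bool = False) -> np.ndarray:
        """Predict raw-scale mood for every example in ``data``.

        For ``separate_*`` kinds an unseen patient raises
        :class:`ColdStartError`; with ``allow_missing=True`` those
        predictions come back as NaN instead (callers exclude and count
        them).
        """
        if list(data.feature_names) != self.feature_names:
            raise ValidationError("feature layout differs from the fitted model")
        n = data.n_examples
        if self.kind == "last_observed":
            lo, hi = PREDICTOR_RANGES["mood"]
            return data.X[:, self.state["mood0_col"]] * (hi - lo) + lo
        if self.kind == "pooled_mean":
            return np.full(n, self.state["mean"])
        if self.kind in ("pooled_ridge", "pooled_gbt"):
            return np.asarray(self.state["model"].predict(data.X), dtype=float)

        # separate variants: dispatch per patient id
        out = np.full(n, np.nan)
        sub = self.state["per_patient"]
        for g, pid in enumerate(data.patient_ids):
            mask = data.patient_index == g
            if not mask.any():
                continue
            if pid not in sub:
                if not allow_missing:
                    raise ColdStartError(
                        f"{self.kind}: cold-start unsupported for unseen patient {pid!r}"
                    )
                continue
            if self.kind == "separate_mean":
                out[mask] = sub[pid]
            else:
                out[mask] = sub[pid].predict(data.X[mask])
        return out


def fit_baseline(kind: str, data: ForecastDataset) -> BaselineModel:
    """Fit one baseline forecaster on a windowed dataset."""
    if kind not in BASELINE_KINDS:
        raise ValidationError(f"unknown baseline kind {kind!r}")
    if data.n_examples == 0:
        raise ValidationError("empty dataset")
    state: dict[str, Any] = {}
    hyper: dict[str, Any] = {}

    if kind == "last_observed":
        state["mood0_col"] = data.feature_names.index("mood@0")
    elif kind == "pooled_mean":
        state["mean"] = float(np.mean(data.y))
    elif kind in ("pooled_ridge", "pooled_gbt"):
        model = _make_regressor(kind)
        model.fit(data.X, data.y)
        state["model"] = model
        hyper = RIDGE_PARAMS if kind == "pooled_ridge" else GBT_PARAMS
    else:
        per: dict[str, Any] = {}
        for g, pid in enumerate(data.patient_ids):
            mask = data.patient_index == g
            if not mask.any():
                continue
            if kind == "separate_mean":
                per[pid] = float(np.mean(data.y[mask]))
            else:
                model = _make_regressor(kind)
                model.fit(data.X[mask], data.y[mask])
                per[pid] = model
        state["per_patient"] = per
        if kind != "separate_mean":
            hyper = RIDGE_PARAMS if kind == "separate_ridge" else GBT_PARAMS

    return BaselineModel(
        kind=kind,
        feature_names=list(data.feature_names),
        state=state,
        hyperparams=dict(hyper),
    )
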