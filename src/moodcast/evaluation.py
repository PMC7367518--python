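"""Time-series cross-validation, metrics, sweeps and feature importance.

Two temporal validation schemes mirror two deployment scenarios:

* **leave-all-out** — every patient's timeline is cut into T consecutive
  partitions (anchored at that patient's own first record); fold k tests
  on partition k pooled across patients and trains on everything before
  it.  The first partition is never a test set.  This emulates a cohort
  that starts monitoring together with no prior data.
* **leave-one-out** — one fold per held-out patient: their first
  ``train_period`` days join all other patients' data for training, and
  the following ``test_period`` days are the test set.  This emulates a
  new patient joining an established population (the cold-start setting).

An example belongs to the fold of its *target* date, so a training
example's target can never postdate a same-patient test target within a
fold; ``validate_plan`` asserts this on every plan and ``run_cv`` refuses
corrupted plans.  Metrics are pooled across all folds' test predictions
before R^2 and RMSE are computed (never averaged over folds).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .baselines import BASELINE_KINDS, fit_baseline
from .exceptions import ConfigurationError, LeakageError, ValidationError
from .hierarchical import (
    HierLinearPosterior,
    fit_hier_linear,
    fit_hier_ordinal,
    point_predictions,
)
from .preprocessing import ForecastDataset, build_windows
from .records import PatientSeries
from .sampler import McmcConfig

__all__ = [
    "Fold",
    "SplitPlan",
    "ModelSpec",
    "CVResult",
    "make_leave_all_out_splits",
    "make_leave_one_out_splits",
    "validate_plan",
    "r_squared",
    "rmse",
    "run_cv",
    "window_size_sweep",
    "horizon_sweep",
    "feature_importance",
    "default_model_specs",
]

logger = logging.getLogger(__name__)

HIER_KINDS = ("hier_linear", "hier_ordinal")


@dataclass
class Fold:
    name: str
    train: np.ndarray  # example indices
    test: np.ndarray


@dataclass
class SplitPlan:
    """A resolved cross-validation plan over one windowed dataset."""

    scheme: str
    folds: list[Fold]
    params: dict
    notices: list[str] = field(default_factory=list)
    excluded_patients: list[str] = field(default_factory=list)


def _partition_index(data: ForecastDataset, partition_length: int) -> np.ndarray:
    """0-based partition of each example's target date within its patient's
    timeline (anchored at that patient's first observed record)."""
    first = np.array(
        [data.patient_first_date[data.patient_ids[g]].to_datetime64() for g in range(data.n_patients)],
        dtype="datetime64[D]",
    )
    offset = (data.target_dates - first[data.patient_index]).astype("timedelta64[D]").astype(int)
    return offset // partition_length


def make_leave_all_out_splits(
    data: ForecastDataset, T: int, partition_length: int = 7
) -> SplitPlan:
    """Consecutive-partition CV pooled across patients: T-1 folds, fold k
    testing on partition k and training on partitions before it."""
    if T < 2:
        raise ConfigurationError("T must be >= 2")
    if partition_length < 1:
        raise ConfigurationError("partition_length must be >= 1")
    part = _partition_index(data, partition_length)
    folds = []
    notices = []
    for k in range(1, T):
        test = np.nonzero(part == k)[0]
        train = np.nonzero(part < k)[0]
        if len(test) == 0 or len(train) == 0:
            msg = f"fold {k}: dropped (train={len(train)}, test={len(test)} examples)"
            notices.append(msg)
            logger.info("leave_all_out %s", msg)
            continue
        folds.append(Fold(name=f"partition_{k}", train=train, test=test))
    return SplitPlan(
        scheme="leave_all_out",
        folds=folds,
        params={"T": T, "partition_length": partition_length},
        notices=notices,
    )


def make_leave_one_out_splits(
    data: ForecastDataset, train_period: int = 14, test_period: int = 154
) -> SplitPlan:
    """Held-out-patient CV: the patient's first ``train_period`` days pool
    with all data from every other patient; their next ``test_period``
    days are the test set.  Patients with no test examples are excluded
    and reported."""
    if train_period < 1:
        raise ConfigurationError("train_period must be >= 1")
    if test_period < 1:
        raise ConfigurationError("test_period must be >= 1")
    first = np.array(
        [data.patient_first_date[data.patient_ids[g]].to_datetime64() for g in range(data.n_patients)],
        dtype="datetime64[D]",
    )
    day = (data.target_dates - first[data.patient_index]).astype("timedelta64[D]").astype(int)
    folds = []
    excluded = []
    notices = []
    for g, pid in enumerate(data.patient_ids):
        own = data.patient_index == g
        own_train = own & (day < train_period)
        own_test = own & (day >= train_period) & (day < train_period + test_period)
        if not own_test.any():
            excluded.append(pid)
            continue
        train = np.nonzero(~own | own_train)[0]
        test = np.nonzero(own_test)[0]
        folds.append(Fold(name=f"holdout_{pid}", train=train, test=test))
    if excluded:
        msg = f"{len(excluded)} patient(s) without test-period examples excluded"
        notices.append(msg)
        logger.info("leave_one_out %s: %s", msg, excluded)
    return SplitPlan(
        scheme="leave_one_out",
        folds=folds,
        params={"train_period": train_period, "test_period": test_period},
        notices=notices,
        excluded_patients=excluded,
    )


def validate_plan(plan: SplitPlan, data: ForecastDataset) -> None:
    """Assert the no-future-training invariants; raise LeakageError.

    For every fold and every patient with test examples in it: the fold's
    training examples of that patient must all have target dates strictly
    before that patient's earliest test target date, and train/test index
    sets must be disjoint.
    """
    target = data.target_dates
    for fold in plan.folds:
        if np.intersect1d(fold.train, fold.test).size:
            raise LeakageError(f"{plan.scheme}/{fold.name}: train and test examples overlap")
        test_patients = np.unique(data.patient_index[fold.test])
        for g in test_patients:
            own_test = fold.test[data.patient_index[fold.test] == g]
            own_train = fold.train[data.patient_index[fold.train] == g]
            if len(own_train) == 0:
                continue
            if target[own_train].max() >= target[own_test].min():
                raise LeakageError(
                    f"{plan.scheme}/{fold.name}: patient {data.patient_ids[g]!r} has a "
                    "training target on/after a test target"
                )
        if plan.scheme == "leave_one_out":
            # the held-out patient may contribute at most train_period days
            first = data.patient_first_date
            limit = np.timedelta64(plan.params["train_period"], "D")
            for g in test_patients:
                own_train = fold.train[data.patient_index[fold.train] == g]
                if len(own_train) == 0:
                    continue
                start = first[data.patient_ids[g]].to_datetime64()
                if (target[own_train] - start).max() >= limit:
                    raise LeakageError(
                        f"{plan.scheme}/{fold.name}: held-out patient trains past "
                        f"their first {plan.params['train_period']} days"
                    )


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def r_squared(y_true, y_pred) -> float:
    """Predicted coefficient of determination, 1 - SS_res/SS_tot.

    The reference mean is the mean of ``y_true`` over the pooled test set.
    Negative values mean "worse than predicting that mean"; zero variance
    in ``y_true`` makes the ratio undefined and returns NaN
    (not applicable).
    """
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if yt.shape != yp.shape or yt.size == 0:
        raise ValidationError("y_true and y_pred must have equal non-zero length")
    ss_tot = float(np.sum((yt - yt.mean()) ** 2))
    if ss_tot == 0.0:
        return float("nan")
    return 1.0 - float(np.sum((yt - yp) ** 2)) / ss_tot


def rmse(y_true, y_pred) -> float:
    """Root mean squared error."""
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if yt.shape != yp.shape or yt.size == 0:
        raise ValidationError("y_true and y_pred must have equal non-zero length")
    return float(np.sqrt(np.mean((yt - yp) ** 2)))


# ---------------------------------------------------------------------------
# model specs and the CV engine
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """One model entry in a CV comparison."""

    name: str
    kind: str  # a baseline kind or "hier_linear" / "hier_ordinal"
    mcmc: McmcConfig | None = None

    def __post_init__(self) -> None:
        if self.kind not in BASELINE_KINDS + HIER_KINDS:
            raise ConfigurationError(f"unknown model kind {self.kind!r}")


def default_model_specs(mcmc: McmcConfig | None = None) -> list[ModelSpec]:
    """The full comparison suite: naive baselines, pooled/separate
    regressors and both hierarchical models."""
    mcmc = mcmc or McmcConfig()
    specs = [ModelSpec(k.replace("_", " "), k) for k in BASELINE_KINDS]
    specs.append(ModelSpec("hierarchical linear", "hier_linear", mcmc=mcmc))
    specs.append(ModelSpec("hierarchical ordinal", "hier_ordinal", mcmc=mcmc))
    return specs


@dataclass
class CVResult:
    """Pooled cross-validation outcome.

    ``table`` holds one row per model (scheme, w, h, r2, rmse, n_test,
    n_folds, n_excluded, mean_abs_dev_from_train_mean); ``predictions``
    every pooled test prediction for audit.
    """

    table: pd.DataFrame
    predictions: pd.DataFrame
    scheme: str
    w: int
    h: int


def _fit_and_predict(spec: ModelSpec, train: ForecastDataset, test: ForecastDataset, fold_idx: int):
    if spec.kind in HIER_KINDS:
        mcmc = spec.mcmc or McmcConfig()
        mcmc = replace(mcmc, seed=mcmc.seed + 101 * fold_idx)
        if spec.kind == "hier_linear":
            posterior = fit_hier_linear(train, mcmc)
        else:
            posterior = fit_hier_ordinal(train, mcmc)
        return point_predictions(posterior, test)
    model = fit_baseline(spec.kind, train)
    return model.predict(test, allow_missing=True)


def run_cv(
    specs: Sequence[ModelSpec],
    plan: SplitPlan,
    data: ForecastDataset,
) -> CVResult:
    """Fit every model spec per fold, pool test predictions, score once.

    Models that cannot predict some test examples (separate models facing
    an unseen patient) have those pairs excluded and counted in
    ``n_excluded``.  The plan is leakage-validated before any fit; a
    corrupted plan raises :class:`LeakageError`.
    """
    validate_plan(plan, data)
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ConfigurationError("duplicate model names in specs")

    rows = {s.name: {"y_true": [], "y_pred": [], "pid": [], "fold": [], "anchor": []} for s in specs}
    train_means = []
    for fold_idx, fold in enumerate(plan.folds):
        train = data.subset(fold.train)
        test = data.subset(fold.test)
        train_means.append(float(np.mean(train.y)))
        for spec in specs:
            preds = _fit_and_predict(spec, train, test, fold_idx)
            r = rows[spec.name]
            r["y_true"].append(test.y)
            r["y_pred"].append(np.asarray(preds, dtype=float))
            r["pid"].append([test.patient_ids[g] for g in test.patient_index])
            r["fold"].append(np.full(test.n_examples, fold_idx))
            r["anchor"].append(test.anchor_dates)

    table_rows = []
    pred_frames = []
    for spec in specs:
        r = rows[spec.name]
        y_true = np.concatenate(r["y_true"])
        y_pred = np.concatenate(r["y_pred"])
        fold_ids = np.concatenate(r["fold"]).astype(int)
        pids = np.concatenate([np.asarray(p, dtype=object) for p in r["pid"]])
        anchors = np.concatenate(r["anchor"])
        valid = ~np.isnan(y_pred)
        n_excluded = int((~valid).sum())
        dev = float(
            np.mean(np.abs(y_pred[valid] - np.asarray(train_means)[fold_ids[valid]]))
        ) if valid.any() else float("nan")
        table_rows.append(
            {
                "model": spec.name,
                "scheme": plan.scheme,
                "w": data.w,
                "h": data.h,
                "r2": r_squared(y_true[valid], y_pred[valid]) if valid.any() else float("nan"),
                "rmse": rmse(y_true[valid], y_pred[valid]) if valid.any() else float("nan"),
                "n_test": int(valid.sum()),
                "n_folds": len(plan.folds),
                "n_excluded": n_excluded,
                "mean_abs_dev_from_train_mean": dev,
            }
        )
        pred_frames.append(
            pd.DataFrame(
                {
                    "model": spec.name,
                    "fold": fold_ids,
                    "patient_id": pids,
                    "anchor_date": anchors,
                    "y_true": y_true,
                    "y_pred": y_pred,
                }
            )
        )
    return CVResult(
        table=pd.DataFrame(table_rows),
        predictions=pd.concat(pred_frames, ignore_index=True),
        scheme=plan.scheme,
        w=data.w,
        h=data.h,
    )


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------


def _make_plan(data: ForecastDataset, scheme: str, scheme_params: dict | None) -> SplitPlan:
    params = dict(scheme_params or {})
    if scheme == "leave_all_out":
        return make_leave_all_out_splits(
            data, T=params.get("T", 24), partition_length=params.get("partition_length", 7)
        )
    if scheme == "leave_one_out":
        return make_leave_one_out_splits(
            data,
            train_period=params.get("train_period", 14),
            test_period=params.get("test_period", 154),
        )
    raise ConfigurationError(f"unknown scheme {scheme!r}")


def window_size_sweep(
    series: Sequence[PatientSeries],
    specs: Sequence[ModelSpec],
    w_values: Sequence[int] = tuple(range(1, 8)),
    h: int = 1,
    scheme: str = "leave_all_out",
    scheme_params: dict | None = None,
) -> pd.DataFrame:
    """Rerun CV per window size (datasets differ per w because longer
    windows require longer complete histories); returns the tidy table
    with one row per (model, w) and the per-w dataset size."""
    out = []
    for w in w_values:
        data = build_windows(series, w=w, h=h)
        plan = _make_plan(data, scheme, scheme_params)
        result = run_cv(specs, plan, data)
        t = result.table.copy()
        t["n_examples"] = data.n_examples
        out.append(t)
    return pd.concat(out, ignore_index=True)


def horizon_sweep(
    series: Sequence[PatientSeries],
    specs: Sequence[ModelSpec],
    w: int = 4,
    h_values: Sequence[int] = tuple(range(1, 8)),
    scheme: str = "leave_all_out",
    scheme_params: dict | None = None,
) -> pd.DataFrame:
    """Rerun CV per forecast horizon at fixed window size.

    Besides R^2/RMSE the table carries ``mean_abs_dev_from_train_mean``,
    the mean absolute deviation of a model's predictions from the
    training-target mean — as the horizon grows the predictable signal
    shrinks and forecasts regress toward that mean.
    """
    out = []
    for h in h_values:
        data = build_windows(series, w=w, h=h)
        plan = _make_plan(data, scheme, scheme_params)
        result = run_cv(specs, plan, data)
        t = result.table.copy()
        t["n_examples"] = data.n_examples
        out.append(t)
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# feature importance
# ---------------------------------------------------------------------------


def feature_importance(posterior: HierLinearPosterior) -> pd.DataFrame:
    """Importance as the absolute t-statistic of individual-level weights.

    For each patient j and weight, t = posterior mean / posterior SD of
    beta_j; the table reports the mean and SD over patients of |t| per
    (item, lag), sorted by mean |t| descending.  A weight with zero
    posterior SD yields NaN (degenerate posterior, not applicable).
    """
    beta = posterior.draws["beta"]  # (D, J, P)
    mean = beta.mean(axis=0)
    sd = beta.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_abs = np.abs(np.where(sd > 0, mean / sd, np.nan))
    items = [name.split("@")[0] for name in posterior.feature_names]
    lags = [int(name.split("@")[1]) for name in posterior.feature_names]
    df = pd.DataFrame(
        {
            "item": items,
            "lag": lags,
            "mean_abs_t": np.nanmean(t_abs, axis=0) if t_abs.size else [],
            "sd_abs_t": np.nanstd(t_abs, axis=0, ddof=1) if t_abs.shape[0] > 1 else np.nan,
        }
    )
    return df.sort_values("mean_abs_t", ascending=False, ignore_index=True)
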