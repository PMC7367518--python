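"""CV splitters, leakage guards, metrics, the CV engine, sweeps and
feature importance."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_linear_dataset, make_series
from moodcast import evaluation
from moodcast.evaluation import (
    Fold,
    ModelSpec,
    SplitPlan,
    feature_importance,
    make_leave_all_out_splits,
    make_leave_one_out_splits,
    r_squared,
    rmse,
    run_cv,
    validate_plan,
    window_size_sweep,
)
from moodcast.exceptions import ConfigurationError, LeakageError, ValidationError
from moodcast.hierarchical import HierLinearPosterior
from moodcast.preprocessing import build_windows, feature_labels
from moodcast.sampler import McmcConfig
from moodcast.synthetic import PopulationConfig, generate_population


def _two_patient_windows(n_days=21, w=2, h=1):
    series = [make_series("A", days=range(1, n_days + 1)),
              make_series("B", days=range(1, n_days + 1))]
    return build_windows(series, w=w, h=h)


# ---------------------------------------------------------------------------
# splitters
# ---------------------------------------------------------------------------


def test_leave_all_out_enumeration_21_days():
    data = _two_patient_windows(21)
    plan = make_leave_all_out_splits(data, T=3, partition_length=7)
    assert len(plan.folds) == 2
    target_day = (data.target_dates - np.datetime64("2020-01-01")).astype(int) + 1
    f0 = plan.folds[0]
    # fold 1 trains on targets in days 1-7 of both patients, tests on days 8-14
    assert set(target_day[f0.train]) <= set(range(1, 8))
    assert set(target_day[f0.test]) <= set(range(8, 15))
    assert len(set(data.patient_index[f0.test])) == 2
    validate_plan(plan, data)


def test_leave_all_out_minimal_T_gives_single_fold():
    data = _two_patient_windows(21)
    plan = make_leave_all_out_splits(data, T=2, partition_length=7)
    assert len(plan.folds) == 1


def test_leave_all_out_rejects_small_T():
    data = _two_patient_windows(14)
    with pytest.raises(ConfigurationError):
        make_leave_all_out_splits(data, T=1)


def test_leave_all_out_ordering_invariant_by_construction():
    data = _two_patient_windows(35, w=3, h=2)
    plan = make_leave_all_out_splits(data, T=5, partition_length=7)
    target = data.target_dates
    for fold in plan.folds:
        for g in np.unique(data.patient_index[fold.test]):
            tr = fold.train[data.patient_index[fold.train] == g]
            te = fold.test[data.patient_index[fold.test] == g]
            if len(tr):
                assert target[tr].max() < target[te].min()


def test_leave_one_out_enumeration():
    series = [make_series("A", days=range(1, 101)),
              make_series("B", days=range(1, 101)),
              make_series("C", days=range(1, 101))]
    data = build_windows(series, w=2, h=1)
    plan = make_leave_one_out_splits(data, train_period=14, test_period=154)
    assert len(plan.folds) == 3
    fold = [f for f in plan.folds if f.name == "holdout_A"][0]
    day = (data.target_dates - np.datetime64("2020-01-01")).astype(int)
    own = data.patient_index == 0
    # held-out patient: targets in days 0..13 train, 14.. test
    own_train = fold.train[data.patient_index[fold.train] == 0]
    assert day[own_train].max() < 14
    assert set(fold.test) == set(np.nonzero(own & (day >= 14))[0])
    # everyone else fully in training
    others = np.nonzero(~own)[0]
    assert set(others) <= set(fold.train)
    validate_plan(plan, data)


def test_leave_one_out_excludes_short_series_and_reports():
    series = [make_series("A", days=range(1, 101)),
              make_series("B", days=range(1, 11))]  # nothing after day 14
    data = build_windows(series, w=2, h=1)
    plan = make_leave_one_out_splits(data)
    assert plan.excluded_patients == ["B"]
    assert len(plan.folds) == 1
    assert plan.notices


def test_validate_plan_rejects_corrupted_plan():
    data = _two_patient_windows(21)
    plan = make_leave_all_out_splits(data, T=3, partition_length=7)
    fold = plan.folds[0]
    # move a test example into training: future information leaks
    bad = SplitPlan(
        scheme=plan.scheme,
        folds=[Fold(fold.name, np.append(fold.train, fold.test[-1]), fold.test)],
        params=plan.params,
    )
    with pytest.raises(LeakageError):
        validate_plan(bad, data)
    with pytest.raises(LeakageError):
        run_cv([ModelSpec("mean", "pooled_mean")], bad, data)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def test_r_squared_known_values():
    assert r_squared([1, 2, 3], [1, 2, 3]) == 1.0
    assert r_squared([0, 0, 2, 2], [0, 1, 1, 2]) == pytest.approx(0.5)
    y = np.array([0.0, 1.0, 2.0, 5.0])
    assert r_squared(y, np.full(4, y.mean())) == pytest.approx(0.0)
    assert np.isnan(r_squared([1, 1, 1], [1, 0, 1]))  # zero variance: n/a


def test_rmse_known_values_and_symmetry():
    assert rmse([1, 2], [1, 2]) == 0.0
    assert rmse([0, 2], [0, 0]) == pytest.approx(np.sqrt(2))
    rng = np.random.default_rng(0)
    y, p = rng.random(20), rng.random(20)
    perm = rng.permutation(20)
    assert rmse(y, p) == pytest.approx(rmse(y[perm], p[perm]))


def test_metric_identity_on_pooled_predictions():
    rng = np.random.default_rng(1)
    y, p = rng.random(50), rng.random(50)
    ss_tot = np.sum((y - y.mean()) ** 2)
    assert r_squared(y, p) == pytest.approx(1 - rmse(y, p) ** 2 * len(y) / ss_tot)


def test_metrics_reject_bad_shapes():
    with pytest.raises(ValidationError):
        rmse([1, 2], [1])
    with pytest.raises(ValidationError):
        r_squared([], [])


# ---------------------------------------------------------------------------
# the CV engine
# ---------------------------------------------------------------------------


def test_run_cv_oracle_model_scores_perfectly(monkeypatch):
    moods = list(np.tile([-1.0, 0.0, 0.5, 1.0], 7))
    series = [make_series("A", days=range(1, 29), mood=moods),
              make_series("B", days=range(1, 29), mood=moods[::-1])]
    data = build_windows(series, w=2, h=1)
    plan = make_leave_all_out_splits(data, T=4, partition_length=7)

    def oracle(spec, train, test, fold_idx):
        return test.y.copy()

    monkeypatch.setattr(evaluation, "_fit_and_predict", oracle)
    result = run_cv([ModelSpec("oracle", "pooled_mean")], plan, data)
    row = result.table.iloc[0]
    assert row["r2"] == pytest.approx(1.0)
    assert row["rmse"] == pytest.approx(0.0)


def test_run_cv_pooled_mean_r2_near_zero():
    cfg = PopulationConfig(n_patients=10, n_days=60, adherence=1.0, seed=2)
    data = build_windows(generate_population(cfg), w=1, h=1)
    plan = make_leave_all_out_splits(data, T=6, partition_length=7)
    result = run_cv([ModelSpec("pooled mean", "pooled_mean")], plan, data)
    assert result.table.iloc[0]["r2"] == pytest.approx(0.0, abs=0.1)


def test_run_cv_counts_unpredictable_pairs_for_separate_models():
    series = [make_series("A", days=range(1, 29)),
              make_series("B", days=range(8, 29))]  # B absent from partition 0
    data = build_windows(series, w=1, h=1)
    # patient B's partitions are anchored at their own first record, so both
    # patients have training data in every fold here; force the cold start by
    # holding out a patient id instead
    train = data.subset(np.nonzero(data.patient_index == 0)[0])
    test = data.subset(np.nonzero(data.patient_index == 1)[0])
    plan = SplitPlan(
        scheme="leave_all_out",
        folds=[Fold("manual", np.nonzero(data.patient_index == 0)[0],
                    np.nonzero(data.patient_index == 1)[0])],
        params={},
    )
    result = run_cv([ModelSpec("sep mean", "separate_mean"),
                     ModelSpec("pooled mean", "pooled_mean")], plan, data)
    sep = result.table[result.table.model == "sep mean"].iloc[0]
    pooled = result.table[result.table.model == "pooled mean"].iloc[0]
    assert sep["n_excluded"] == test.n_examples and sep["n_test"] == 0
    assert pooled["n_excluded"] == 0


def test_run_cv_is_deterministic(fast_mcmc):
    cfg = PopulationConfig(n_patients=6, n_days=40, adherence=1.0, seed=5)
    data = build_windows(generate_population(cfg), w=1, h=1)
    plan = make_leave_all_out_splits(data, T=3, partition_length=7)
    specs = [ModelSpec("hier", "hier_linear", mcmc=fast_mcmc),
             ModelSpec("ridge", "pooled_ridge")]
    a = run_cv(specs, plan, data)
    b = run_cv(specs, plan, data)
    pd.testing.assert_frame_equal(a.table, b.table)


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------


def test_window_sweep_shape_and_mean_model_stability():
    cfg = PopulationConfig(n_patients=8, n_days=60, adherence=1.0, seed=7)
    series = generate_population(cfg)
    specs = [ModelSpec("pooled mean", "pooled_mean"),
             ModelSpec("last observed", "last_observed")]
    table = window_size_sweep(series, specs, w_values=[1, 2, 3], h=1,
                              scheme_params={"T": 6, "partition_length": 7})
    assert len(table) == 3 * len(specs)
    assert set(table["w"]) == {1, 2, 3}
    mean_rows = table[table.model == "pooled mean"]
    # fully observed data: the mean model's RMSE moves only via dataset size
    assert mean_rows["rmse"].max() - mean_rows["rmse"].min() < 0.1 * mean_rows["rmse"].min()


def test_horizon_sweep_shape(fast_mcmc):
    cfg = PopulationConfig(n_patients=8, n_days=60, adherence=1.0, seed=8)
    series = generate_population(cfg)
    specs = [ModelSpec("last observed", "last_observed"),
             ModelSpec("pooled ridge", "pooled_ridge")]
    table = evaluation.horizon_sweep(series, specs, w=1, h_values=[1, 3],
                                     scheme_params={"T": 6, "partition_length": 7})
    assert len(table) == 2 * len(specs)
    assert "mean_abs_dev_from_train_mean" in table.columns
    assert table["mean_abs_dev_from_train_mean"].notna().all()


# ---------------------------------------------------------------------------
# feature importance
# ---------------------------------------------------------------------------


def _posterior_from_beta_draws(beta):
    d, j, p = beta.shape
    draws = {
        "mu_alpha": np.zeros(d),
        "mu_beta": beta.mean(axis=1),
        "tau_alpha": np.full(d, 0.1),
        "tau_beta": np.full((d, p), 0.1),
        "sigma": np.full(d, 0.1),
        "alpha": np.zeros((d, j)),
        "beta": beta,
    }
    return HierLinearPosterior(
        draws=draws, patients=[f"P{i}" for i in range(j)],
        feature_names=feature_labels(1), config=McmcConfig(chains=1, iterations=2),
        priors={},
    )


def test_importance_hand_computed_t_statistic():
    beta = np.zeros((6, 1, 12))
    beta[:, 0, 0] = [1, 1, 1, 3, 3, 3]  # mean 2, sd 1.0954 -> |t| = 1.826
    table = feature_importance(_posterior_from_beta_draws(beta))
    row = table[(table["item"] == "mood") & (table["lag"] == 0)].iloc[0]
    assert row["mean_abs_t"] == pytest.approx(2 / 1.0954451, rel=1e-4)
    assert table.iloc[0]["item"] == "mood"  # sorted descending


def test_importance_zero_for_symmetric_draws():
    beta = np.zeros((8, 2, 12))
    beta[:, :, 3] = np.array([1, -1, 2, -2, 1, -1, 2, -2])[:, None]
    table = feature_importance(_posterior_from_beta_draws(beta))
    row = table[(table["item"] == "anxiety") & (table["lag"] == 0)].iloc[0]
    assert row["mean_abs_t"] == pytest.approx(0.0, abs=1e-12)


def test_importance_has_one_row_per_item_lag(fast_mcmc):
    rng = np.random.default_rng(20)
    data, _ = make_linear_dataset(rng, j_count=3, per_patient=10)
    from moodcast.hierarchical import fit_hier_linear

    table = feature_importance(fit_hier_linear(data, fast_mcmc))
    assert len(table) == 12
    assert (table["mean_abs_t"] >= 0).all()
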