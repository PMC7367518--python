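"""Hierarchical forecasters: gradients, ordered-logistic pmf, recovery,
prediction contracts and posterior-predictive replication."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import logistic

from conftest import make_linear_dataset, make_ordinal_dataset
from moodcast.exceptions import ValidationError
from moodcast.hierarchical import (
    HierLinearPosterior,
    _linear_target,
    _ordinal_target,
    fit_hier_linear,
    fit_hier_ordinal,
    ordered_logistic_pmf,
    posterior_predictive_replicate,
    predict,
)
from moodcast.items import MOOD_LEVELS
from moodcast.preprocessing import feature_labels
from moodcast.sampler import McmcConfig


def _finite_diff(f, theta, eps=1e-6):
    num = np.zeros_like(theta)
    for i in range(len(theta)):
        tp, tm = theta.copy(), theta.copy()
        tp[i] += eps
        tm[i] -= eps
        num[i] = (f(tp)[0] - f(tm)[0]) / (2 * eps)
    return num


@pytest.mark.parametrize("fix_tau,fix_sigma", [(None, None), (0.01, None), (None, 0.3)])
def test_linear_log_posterior_gradient_matches_finite_differences(fix_tau, fix_sigma):
    rng = np.random.default_rng(2)
    data, _ = make_linear_dataset(rng, j_count=4, per_patient=8)
    f, dim, _, init, _ = _linear_target(data, fix_tau, fix_sigma)
    theta = np.asarray(init) + 0.1 * rng.standard_normal(dim)
    _, grad = f(theta)
    num = _finite_diff(f, theta)
    np.testing.assert_allclose(grad, num, atol=5e-6, rtol=1e-5)


def test_ordinal_log_posterior_gradient_matches_finite_differences():
    rng = np.random.default_rng(3)
    data = make_ordinal_dataset(rng, j_count=4, per_patient=15)
    f, dim, _, init, _ = _ordinal_target(data)
    theta = np.asarray(init) + 0.1 * rng.standard_normal(dim)
    _, grad = f(theta)
    num = _finite_diff(f, theta)
    np.testing.assert_allclose(grad, num, atol=5e-6, rtol=1e-5)


# ---------------------------------------------------------------------------
# ordered logistic pmf
# ---------------------------------------------------------------------------


def test_pmf_symmetric_binary_case():
    np.testing.assert_allclose(ordered_logistic_pmf(0.0, [0.0]), [0.5, 0.5])


def test_pmf_closed_form_log3():
    probs = ordered_logistic_pmf(np.log(3.0), [0.0])
    np.testing.assert_allclose(probs, [0.25, 0.75], atol=1e-12)


def test_pmf_rejects_unordered_cutpoints():
    with pytest.raises(ValidationError):
        ordered_logistic_pmf(0.0, [1.0, 0.5])


@given(
    st.floats(min_value=-20, max_value=20),
    st.lists(st.floats(min_value=-10, max_value=10), min_size=1, max_size=8, unique=True),
)
def test_pmf_normalises_and_matches_logistic_cdf(z, cuts):
    cuts = np.sort(np.asarray(cuts))
    probs = ordered_logistic_pmf(z, cuts)
    assert probs.shape == (len(cuts) + 1,)
    assert np.all(probs >= 0)
    assert abs(probs.sum() - 1.0) < 1e-12
    # independent closed form: differences of scipy logistic CDFs
    edges = np.concatenate([[-np.inf], cuts, [np.inf]])
    expected = logistic.cdf(z - edges[:-1]) - logistic.cdf(z - edges[1:])
    np.testing.assert_allclose(probs, expected, atol=1e-12)


# ---------------------------------------------------------------------------
# hierarchical linear fitting
# ---------------------------------------------------------------------------


def test_linear_recovers_known_weight_and_noise():
    # data generated from the model: dominant weight 2.0 on the first
    # predictor, noise SD 0.10, negligible between-patient spread
    rng = np.random.default_rng(11)
    mu_beta = np.zeros(12)
    mu_beta[0] = 2.0
    data, truth = make_linear_dataset(
        rng, j_count=10, per_patient=50, mu_beta=mu_beta, tau_alpha=0.01,
        tau_beta=0.01, sigma=0.10,
    )
    post = fit_hier_linear(data, McmcConfig(chains=2, iterations=800, seed=4))
    sigma_mean = post.draws["sigma"].mean()
    assert 0.07 <= sigma_mean <= 0.13
    assert post.draws["mu_beta"][:, 0].mean() == pytest.approx(2.0, abs=0.2)


def test_linear_null_data_centers_intercept_at_zero(fast_mcmc):
    rng = np.random.default_rng(5)
    data, _ = make_linear_dataset(
        rng, j_count=1, per_patient=40, mu_beta=np.zeros(12), tau_alpha=0.0,
        tau_beta=0.0, sigma=0.2, mu_alpha=0.0,
    )
    data.X[:] = 0.0
    data.y[:] = 0.0
    post = fit_hier_linear(data, fast_mcmc)
    alpha = post.draws["alpha"][:, 0]
    assert abs(alpha.mean()) <= 2 * alpha.std()


def test_linear_fit_is_deterministic_under_seed(fast_mcmc):
    rng = np.random.default_rng(6)
    data, _ = make_linear_dataset(rng, j_count=3, per_patient=10)
    a = fit_hier_linear(data, fast_mcmc)
    b = fit_hier_linear(data, fast_mcmc)
    np.testing.assert_array_equal(a.draws["beta"], b.draws["beta"])
    np.testing.assert_array_equal(a.draws["sigma"], b.draws["sigma"])


def test_linear_rejects_empty_dataset(fast_mcmc):
    rng = np.random.default_rng(7)
    data, _ = make_linear_dataset(rng, j_count=2, per_patient=5)
    with pytest.raises(ValidationError):
        fit_hier_linear(data.subset(np.array([], dtype=int)), fast_mcmc)


def test_positivity_of_scale_draws(fast_mcmc):
    rng = np.random.default_rng(8)
    data, _ = make_linear_dataset(rng, j_count=4, per_patient=12)
    post = fit_hier_linear(data, fast_mcmc)
    assert np.all(post.draws["sigma"] > 0)
    assert np.all(post.draws["tau_alpha"] > 0)
    assert np.all(post.draws["tau_beta"] > 0)
    assert post.n_draws == fast_mcmc.n_draws


def test_shrinkage_toward_population_with_scarce_data():
    # patients with very few examples get weight estimates closer to the
    # population mean than their separate least-squares estimates are
    rng = np.random.default_rng(9)
    mu_beta = np.zeros(12)
    mu_beta[0] = 1.0
    data, truth = make_linear_dataset(
        rng, j_count=12, per_patient=3, mu_beta=mu_beta, tau_alpha=0.2,
        tau_beta=0.1, sigma=0.3,
    )
    post = fit_hier_linear(data, McmcConfig(chains=2, iterations=600, seed=2))
    mu_hat = post.draws["mu_beta"].mean(axis=0)
    closer = 0
    total = 0
    for j in range(12):
        mask = data.patient_index == j
        X1 = np.column_stack([np.ones(mask.sum()), data.X[mask]])
        sep, *_ = np.linalg.lstsq(X1, data.y[mask], rcond=None)
        beta_hat = post.draws["beta"][:, j, :].mean(axis=0)
        d_hier = np.linalg.norm(beta_hat - mu_hat)
        d_sep = np.linalg.norm(sep[1:] - mu_hat)
        total += 1
        closer += d_hier < d_sep
    assert closer >= 0.9 * total


# ---------------------------------------------------------------------------
# hierarchical ordinal fitting
# ---------------------------------------------------------------------------


def test_ordinal_rejects_off_scale_targets(fast_mcmc):
    rng = np.random.default_rng(10)
    data, _ = make_linear_dataset(rng, j_count=2, per_patient=6)
    data.y[:] = 0.3  # not a valid level
    with pytest.raises(ValidationError):
        fit_hier_ordinal(data, fast_mcmc)


def test_ordinal_two_observed_levels_concentrates_mass(fast_mcmc):
    rng = np.random.default_rng(12)
    data = make_ordinal_dataset(rng, j_count=5, per_patient=30, levels=[0.0, 0.5])
    post = fit_hier_ordinal(data, fast_mcmc)
    report, rep = posterior_predictive_replicate(
        post, data, n_draws=100, seed=0, return_draws=True
    )
    in_observed = np.isin(rep, [0.0, 0.5]).mean()
    assert in_observed >= 0.90
    assert post.level_range == (0.0, 0.5)


def test_ordinal_symmetric_data_gives_symmetric_cutpoints():
    # balanced targets around zero with null features: interior cutpoints
    # should be approximately antisymmetric
    rng = np.random.default_rng(13)
    data = make_ordinal_dataset(rng, j_count=4, per_patient=72)
    data.X[:] = 0.0
    data.y[:] = np.tile(MOOD_LEVELS, len(data.y) // 9 + 1)[: len(data.y)]
    post = fit_hier_ordinal(data, McmcConfig(chains=2, iterations=600, seed=3))
    mu_c = post.draws["mu_c"]
    mean_c = mu_c.mean(axis=0)
    sd_c = mu_c.std(axis=0)
    k = len(mean_c)
    for m in range(k // 2):
        tol = 2 * (sd_c[m] + sd_c[k - 1 - m])
        assert abs(mean_c[m] + mean_c[k - 1 - m]) <= tol


def test_ordinal_cutpoints_strictly_increasing_in_every_draw(fast_mcmc):
    rng = np.random.default_rng(14)
    data = make_ordinal_dataset(rng, j_count=3, per_patient=25)
    post = fit_hier_ordinal(data, fast_mcmc)
    assert np.all(np.diff(post.draws["cutpoints"], axis=-1) > 0)
    assert np.all(np.diff(post.draws["mu_c"], axis=-1) > 0)


def test_ordinal_fit_is_deterministic_under_seed(fast_mcmc):
    rng = np.random.default_rng(15)
    data = make_ordinal_dataset(rng, j_count=2, per_patient=15)
    a = fit_hier_ordinal(data, fast_mcmc)
    b = fit_hier_ordinal(data, fast_mcmc)
    np.testing.assert_array_equal(a.draws["cutpoints"], b.draws["cutpoints"])


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------


def _degenerate_linear_posterior(n_draws=200, p=12, sigma=0.1):
    beta = np.zeros((n_draws, 1, p))
    beta[:, 0, 0] = 2.0
    draws = {
        "mu_alpha": np.ones(n_draws),
        "mu_beta": beta[:, 0, :],
        "tau_alpha": np.full(n_draws, 1e-12),
        "tau_beta": np.full((n_draws, p), 1e-12),
        "sigma": np.full(n_draws, sigma),
        "alpha": np.ones((n_draws, 1)),
        "beta": beta,
    }
    return HierLinearPosterior(
        draws=draws,
        patients=["P00"],
        feature_names=feature_labels(1),
        config=McmcConfig(chains=1, iterations=2),
        priors={},
    )


def test_predict_point_mass_posterior():
    post = _degenerate_linear_posterior()
    x = np.zeros(12)
    x[0] = 0.5
    summary = predict(post, x, patient_id="P00", seed=1)
    assert summary.mean == pytest.approx(2.0)  # 1 + 2 * 0.5
    assert summary.sd == pytest.approx(0.1, rel=0.05)  # noise-driven spread


def test_predict_feature_length_mismatch():
    post = _degenerate_linear_posterior()
    with pytest.raises(ValidationError):
        predict(post, np.zeros(5), patient_id="P00")


def test_predict_unseen_patient_collapses_to_population(fast_mcmc):
    # with tau ~ 0 a cold-start prediction equals an average training
    # patient's prediction up to Monte-Carlo error
    rng = np.random.default_rng(16)
    data, _ = make_linear_dataset(
        rng, j_count=6, per_patient=25, tau_alpha=0.01, tau_beta=0.01, sigma=0.2
    )
    post = fit_hier_linear(data, fast_mcmc)
    x = np.full(12, 0.5)
    seen = predict(post, x, patient_id="P00", seed=2)
    unseen = predict(post, x, patient_id="NEW", seed=2)
    assert unseen.mean == pytest.approx(seen.mean, abs=3 * seen.sd / np.sqrt(post.n_draws) + 0.02)


def test_ordinal_predictions_bounded_by_training_levels(fast_mcmc):
    rng = np.random.default_rng(17)
    data = make_ordinal_dataset(rng, j_count=4, per_patient=30, levels=[-1.0, -0.5, 0.0, 0.5])
    post = fit_hier_ordinal(data, fast_mcmc)
    lo, hi = post.level_range
    for i in range(0, data.n_examples, 7):
        s = predict(post, data.X[i], patient_id=data.patient_ids[data.patient_index[i]])
        assert lo <= s.mean <= hi
        assert s.lower in MOOD_LEVELS and s.upper in MOOD_LEVELS
        assert lo <= s.lower <= s.upper <= hi
    # cold start respects the bound too
    s = predict(post, data.X[0], patient_id="UNSEEN")
    assert lo <= s.lower <= s.mean <= s.upper <= hi


# ---------------------------------------------------------------------------
# posterior predictive replication
# ---------------------------------------------------------------------------


def test_replication_perfect_model_reports_100_percent():
    rng = np.random.default_rng(18)
    n = 60
    post = _degenerate_linear_posterior(n_draws=100, sigma=1e-9)
    from moodcast.preprocessing import ForecastDataset

    X = np.zeros((n, 12))
    X[:, 0] = np.linspace(-2.0, 1.0, n)  # spans both mood tails under the rule
    y = 1.0 + 2.0 * X[:, 0]  # exactly the degenerate posterior's rule
    data = ForecastDataset(
        X=X, y=y, patient_index=np.zeros(n, dtype=int),
        anchor_dates=np.arange(n).astype("datetime64[D]"),
        patient_ids=["P00"], w=1, h=1,
    )
    report = posterior_predictive_replicate(post, data, n_draws=50, seed=0)
    assert report.ratio_below == pytest.approx(100.0)
    assert report.ratio_above == pytest.approx(100.0)
    assert report.observed_below > 0 and report.observed_above > 0


def test_replication_empty_tails_are_not_applicable():
    post = _degenerate_linear_posterior(n_draws=50, sigma=1e-9)
    from moodcast.preprocessing import ForecastDataset

    n = 20
    X = np.zeros((n, 12))
    X[:, 0] = 0.0  # prediction = 1.0 everywhere... keep targets mid-band
    y = np.full(n, 0.0)
    data = ForecastDataset(
        X=X, y=y, patient_index=np.zeros(n, dtype=int),
        anchor_dates=np.arange(n).astype("datetime64[D]"),
        patient_ids=["P00"], w=1, h=1,
    )
    report = posterior_predictive_replicate(post, data, n_draws=20, seed=0)
    assert report.ratio_below is None
    assert report.ratio_above is None


def test_replication_rejects_mismatched_layout(fast_mcmc):
    rng = np.random.default_rng(19)
    data, _ = make_linear_dataset(rng, j_count=2, per_patient=8)
    post = fit_hier_linear(data, fast_mcmc)
    other = make_ordinal_dataset(rng, j_count=2, per_patient=8)
    other.feature_names = feature_labels(2)[:12]  # same length, different labels
    with pytest.raises(ValidationError):
        posterior_predictive_replicate(post, other)
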