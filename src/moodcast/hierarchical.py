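"""Hierarchical Bayesian mood forecasters.

Two partially pooled regression models over windowed self-assessment
features, sharing statistical strength across patients:

* **Linear**: ``y_ji ~ Normal(alpha_j + beta_j' x_ji, sigma)`` with
  per-patient intercepts and weights drawn from population distributions
  ``alpha_j ~ Normal(mu_alpha, tau_alpha)``,
  ``beta_j ~ Normal(mu_beta, tau_beta)``.
* **Ordinal**: the 9-level mood target is treated as an incomplete
  measurement of a latent score ``z_ji = beta_j' x_ji``;
  ``y_ji ~ OrderedLogistic(z_ji, c_j)`` with per-patient ordered cutpoints
  partially pooled across patients.  The model has no intercept — location
  is absorbed by the cutpoints.

Both models are sampled with NUTS in a non-centered parameterization
(individual effects expressed as population mean + scale * standard-normal
residual), which decouples individual parameters from their population
scales and is the standard remedy for the funnel geometry of hierarchical
posteriors.  Weight priors encode the a-priori expectation that lagged mood
is the dominant predictor: mood-lag population parameters get unit-scale
priors, all other items quarter-scale priors.

Cutpoint ordering is enforced by construction: patient cutpoints are
parameterized as a first cutpoint plus positive (exponentiated)
increments, and the hierarchy lives on that unconstrained scale, so every
draw satisfies ``c_1 < ... < c_K-1`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import arviz as az
import numpy as np
from scipy.special import expit

from . import _kernels
from .exceptions import ValidationError
from .items import MOOD_LEVELS
from .preprocessing import ForecastDataset
from .sampler import McmcConfig, nuts_sample

__all__ = [
    "HierLinearPosterior",
    "HierOrdinalPosterior",
    "PredictiveSummary",
    "ReplicationReport",
    "fit_hier_linear",
    "fit_hier_ordinal",
    "ordered_logistic_pmf",
    "predict",
    "posterior_predictive_replicate",
]

RHAT_WARN = 1.05

# prior scales: (mood-lag columns, all other columns)
_MU_BETA_SCALE = (1.0, 0.25)
_TAU_BETA_SCALE = (1.0, 0.25)
_MU_ALPHA_SCALE = 1.0
_TAU_ALPHA_SCALE = 0.25
_SIGMA_SCALE = 0.25
# ordinal cutpoint hierarchy (unconstrained scale: first cutpoint, log-increments)
_MU_CUT_LOC = (-3.0, -0.5)
_MU_CUT_SCALE = (2.0, 1.0)
_TAU_CUT_SCALE = 0.25


def _mood_columns(feature_names: Sequence[str]) -> np.ndarray:
    return np.array([name.split("@")[0] == "mood" for name in feature_names])


def _compact(data: ForecastDataset):
    """Sort examples by patient and build the compact training-patient map."""
    if data.n_examples == 0:
        raise ValidationError("empty dataset")
    order = np.argsort(data.patient_index, kind="stable")
    pidx = data.patient_index[order]
    uniq = np.unique(pidx)
    remap = {int(g): k for k, g in enumerate(uniq)}
    jidx = np.array([remap[int(g)] for g in pidx])
    starts = np.searchsorted(jidx, np.arange(len(uniq)))
    patients = [data.patient_ids[int(g)] for g in uniq]
    return order, jidx, starts, patients


@dataclass
class HierLinearPosterior:
    """Posterior draws of the hierarchical linear forecaster.

    ``draws`` holds flattened per-draw arrays: ``alpha`` (D, J), ``beta``
    (D, J, P), ``sigma`` (D,), ``mu_alpha``, ``mu_beta``, ``tau_alpha``,
    ``tau_beta``.  ``patients`` maps compact index -> patient id.
    """

    draws: dict[str, np.ndarray]
    patients: list[str]
    feature_names: list[str]
    config: McmcConfig
    priors: dict
    diagnostics: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    kind = "hier_linear"

    @property
    def n_draws(self) -> int:
        return len(self.draws["sigma"])

    def patient_pos(self, patient_id: str) -> int | None:
        try:
            return self.patients.index(patient_id)
        except ValueError:
            return None


@dataclass
class HierOrdinalPosterior:
    """Posterior draws of the hierarchical ordinal forecaster.

    ``cutpoints`` (D, J, K-1) are strictly increasing in every draw by
    construction; ``mu_c`` (D, K-1) are the ordered population-typical
    cutpoints and ``tau_c`` the population scales on the unconstrained
    (first cutpoint, log-increment) parameterization.  ``levels`` are the
    K ordinal mood values; ``level_range`` the (min, max) levels seen in
    training, bounding every prediction.
    """

    draws: dict[str, np.ndarray]
    patients: list[str]
    feature_names: list[str]
    levels: np.ndarray
    level_range: tuple[float, float]
    config: McmcConfig
    priors: dict
    diagnostics: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    kind = "hier_ordinal"

    @property
    def n_draws(self) -> int:
        return len(self.draws["mu_beta"])

    def patient_pos(self, patient_id: str) -> int | None:
        try:
            return self.patients.index(patient_id)
        except ValueError:
            return None


def _diagnose(sample_draws: np.ndarray, layout: dict[str, slice], names: Sequence[str]):
    """Split-R-hat and bulk ESS for the named (population) parameter blocks."""
    post = {}
    for name in names:
        block = sample_draws[:, :, layout[name]]
        post[name] = block[..., 0] if block.shape[-1] == 1 else block
    idata = az.from_dict(posterior=post)
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    out = {"rhat": {}, "ess": {}}
    warnings = []
    for name in names:
        r = np.atleast_1d(np.asarray(rhat[name]))
        e = np.atleast_1d(np.asarray(ess[name]))
        out["rhat"][name] = r.tolist()
        out["ess"][name] = e.tolist()
        if np.any(r > RHAT_WARN):
            warnings.append(f"R-hat > {RHAT_WARN} for {name} (max {float(np.nanmax(r)):.3f})")
    return out, warnings


# ---------------------------------------------------------------------------
# hierarchical linear regression
# ---------------------------------------------------------------------------


def _linear_target(data: ForecastDataset, fix_tau: float | None, fix_sigma: float | None):
    """Build the unconstrained log-posterior callback for the linear model.

    Returns ``(logp_grad, dim, layout, init, context)`` where ``layout``
    maps parameter-block names to slices of the unconstrained vector.
    """
    order, jidx, starts, patients = _compact(data)
    X = np.ascontiguousarray(data.X[order])
    y = np.ascontiguousarray(data.y[order])
    n, p = X.shape
    j_count = len(patients)
    ends = np.append(starts, n).astype(np.int64)
    mood = _mood_columns(data.feature_names)
    mu_beta_scale = np.where(mood, *_MU_BETA_SCALE)
    tau_beta_scale = np.where(mood, *_TAU_BETA_SCALE)

    layout: dict[str, slice] = {}
    pos = 0

    def block(name, size):
        nonlocal pos
        layout[name] = slice(pos, pos + size)
        pos += size

    block("mu_alpha", 1)
    block("mu_beta", p)
    if fix_tau is None:
        block("log_tau_alpha", 1)
        block("log_tau_beta", p)
    if fix_sigma is None:
        block("log_sigma", 1)
    block("a_raw", j_count)
    block("b_raw", j_count * p)
    dim = pos

    fix_tau_arg = -1.0 if fix_tau is None else float(fix_tau)
    fix_sigma_arg = -1.0 if fix_sigma is None else float(fix_sigma)

    def logp_grad(theta):
        return _kernels.linear_logp_grad(
            theta,
            X,
            y,
            ends,
            mu_beta_scale,
            tau_beta_scale,
            _MU_ALPHA_SCALE,
            _TAU_ALPHA_SCALE,
            _SIGMA_SCALE,
            fix_tau_arg,
            fix_sigma_arg,
        )

    init = np.zeros(dim)
    init[layout["mu_alpha"]] = float(np.mean(y))
    if fix_tau is None:
        init[layout["log_tau_alpha"]] = np.log(0.1)
        init[layout["log_tau_beta"]] = np.log(0.1)
    if fix_sigma is None:
        init[layout["log_sigma"]] = np.log(np.clip(np.std(y), 0.05, 1.0))

    context = {
        "patients": patients,
        "mu_beta_scale": mu_beta_scale,
        "tau_beta_scale": tau_beta_scale,
    }
    return logp_grad, dim, layout, init, context


def fit_hier_linear(
    data: ForecastDataset,
    mcmc: McmcConfig | None = None,
    fix_tau: float | None = None,
    fix_sigma: float | None = None,
) -> HierLinearPosterior:
    """Fit the hierarchical linear forecaster with NUTS.

    ``fix_tau`` pins both population SDs (tau_alpha and every tau_beta) to
    a constant instead of sampling them; ``fix_sigma`` pins the noise SD.
    Pinning the taus near zero collapses the hierarchy onto a single
    pooled regression, which is useful for closed-form cross-checks.
    Non-convergence (split-R-hat above 1.05 on a population parameter) is
    recorded in ``warnings``, never raised.
    """
    mcmc = mcmc or McmcConfig()
    logp_grad, dim, layout, init, ctx = _linear_target(data, fix_tau, fix_sigma)
    patients = ctx["patients"]
    j_count = len(patients)
    p = len(data.feature_names)
    mu_beta_scale = ctx["mu_beta_scale"]
    tau_beta_scale = ctx["tau_beta_scale"]

    result = nuts_sample(logp_grad, dim, mcmc, initial=init)
    flat = result.flat

    mu_alpha = flat[:, layout["mu_alpha"]][:, 0]
    mu_beta = flat[:, layout["mu_beta"]]
    if fix_tau is None:
        tau_alpha = np.exp(flat[:, layout["log_tau_alpha"]][:, 0])
        tau_beta = np.exp(flat[:, layout["log_tau_beta"]])
    else:
        tau_alpha = np.full(len(flat), fix_tau)
        tau_beta = np.full((len(flat), p), fix_tau)
    sigma = (
        np.exp(flat[:, layout["log_sigma"]][:, 0])
        if fix_sigma is None
        else np.full(len(flat), fix_sigma)
    )
    a_raw = flat[:, layout["a_raw"]]
    b_raw = flat[:, layout["b_raw"]].reshape(len(flat), j_count, p)
    draws = {
        "mu_alpha": mu_alpha,
        "mu_beta": mu_beta,
        "tau_alpha": tau_alpha,
        "tau_beta": tau_beta,
        "sigma": sigma,
        "alpha": mu_alpha[:, None] + tau_alpha[:, None] * a_raw,
        "beta": mu_beta[:, None, :] + tau_beta[:, None, :] * b_raw,
    }

    diag_names = ["mu_alpha", "mu_beta"]
    if fix_sigma is None:
        diag_names.append("log_sigma")
    diagnostics, warnings = _diagnose(result.draws, layout, diag_names)
    diagnostics["divergences"] = result.divergences
    diagnostics["mean_accept"] = result.mean_accept

    priors = {
        "mu_alpha": ["normal", 0.0, _MU_ALPHA_SCALE],
        "mu_beta": ["normal", 0.0, [float(s) for s in mu_beta_scale]],
        "tau_alpha": ["half_normal", _TAU_ALPHA_SCALE] if fix_tau is None else ["fixed", fix_tau],
        "tau_beta": (
            ["half_normal", [float(s) for s in tau_beta_scale]]
            if fix_tau is None
            else ["fixed", fix_tau]
        ),
        "sigma": ["half_normal", _SIGMA_SCALE] if fix_sigma is None else ["fixed", fix_sigma],
    }
    return HierLinearPosterior(
        draws=draws,
        patients=patients,
        feature_names=list(data.feature_names),
        config=mcmc,
        priors=priors,
        diagnostics=diagnostics,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# ordered logistic
# ---------------------------------------------------------------------------


def ordered_logistic_pmf(z, cutpoints) -> np.ndarray:
    """Category probabilities of the ordered-logistic distribution.

    ``P(y = k) = logistic(z - c_{k-1}) - logistic(z - c_k)`` with
    ``c_0 = -inf`` and ``c_K = +inf``.  ``z`` may be scalar or an array;
    ``cutpoints`` has length K-1 (or matching leading shape) and must be
    strictly increasing.  The result sums to 1 along the last axis.
    """
    z = np.asarray(z, dtype=float)
    c = np.asarray(cutpoints, dtype=float)
    if c.ndim == 0 or c.shape[-1] < 1:
        raise ValidationError("need at least one cutpoint")
    if np.any(np.diff(c, axis=-1) <= 0):
        raise ValidationError("cutpoints must be strictly increasing")
    s = expit(z[..., None] - c)  # survivor probabilities P(y > k)
    lead = 1.0 - s[..., :1]
    mid = -np.diff(s, axis=-1)
    tail = s[..., -1:]
    return np.concatenate([lead, mid, tail], axis=-1)


def _cutpoints_from_unconstrained(g: np.ndarray) -> np.ndarray:
    """Map (first cutpoint, log-increments) to ordered cutpoints, last axis."""
    out = np.empty_like(g)
    out[..., 0] = g[..., 0]
    if g.shape[-1] > 1:
        out[..., 1:] = np.exp(g[..., 1:])
    return np.cumsum(out, axis=-1)


def _ordinal_target(data: ForecastDataset):
    """Build the unconstrained log-posterior callback for the ordinal model."""
    if not np.all(np.isin(data.y, MOOD_LEVELS)):
        raise ValidationError("ordinal targets must be on the 9-level mood scale")
    order, jidx, starts, patients = _compact(data)
    X = np.ascontiguousarray(data.X[order])
    y = data.y[order]
    n, p = X.shape
    j_count = len(patients)
    k_count = len(MOOD_LEVELS)
    n_cut = k_count - 1
    cat = np.ascontiguousarray(np.searchsorted(MOOD_LEVELS, y))  # 0-based category
    ends = np.append(starts, n).astype(np.int64)
    mood = _mood_columns(data.feature_names)
    mu_beta_scale = np.where(mood, *_MU_BETA_SCALE)
    tau_beta_scale = np.where(mood, *_TAU_BETA_SCALE)
    mu_cut_loc = np.full(n_cut, _MU_CUT_LOC[1])
    mu_cut_loc[0] = _MU_CUT_LOC[0]
    mu_cut_scale = np.full(n_cut, _MU_CUT_SCALE[1])
    mu_cut_scale[0] = _MU_CUT_SCALE[0]

    layout: dict[str, slice] = {}
    pos = 0

    def block(name, size):
        nonlocal pos
        layout[name] = slice(pos, pos + size)
        pos += size

    block("mu_beta", p)
    block("log_tau_beta", p)
    block("mu_g", n_cut)
    block("log_tau_g", n_cut)
    block("b_raw", j_count * p)
    block("g_raw", j_count * n_cut)
    dim = pos

    def logp_grad(theta):
        return _kernels.ordinal_logp_grad(
            theta,
            X,
            cat,
            ends,
            n_cut,
            mu_beta_scale,
            tau_beta_scale,
            mu_cut_loc,
            mu_cut_scale,
            _TAU_CUT_SCALE,
        )

    # initialise cutpoints at the smoothed marginal quantiles
    counts = np.bincount(cat, minlength=k_count) + 0.5
    cum = np.cumsum(counts)[:-1] / counts.sum()
    c0 = np.log(cum / (1.0 - cum))
    inc0 = np.maximum(np.diff(c0), 0.05)
    init = np.zeros(dim)
    init[layout["mu_g"]] = np.concatenate([[c0[0]], np.log(inc0)])
    init[layout["log_tau_beta"]] = np.log(0.1)
    init[layout["log_tau_g"]] = np.log(0.05)

    context = {
        "patients": patients,
        "y_sorted": y,
        "mu_beta_scale": mu_beta_scale,
        "tau_beta_scale": tau_beta_scale,
        "mu_cut_loc": mu_cut_loc,
        "mu_cut_scale": mu_cut_scale,
    }
    return logp_grad, dim, layout, init, context


def fit_hier_ordinal(data: ForecastDataset, mcmc: McmcConfig | None = None) -> HierOrdinalPosterior:
    """Fit the hierarchical ordered-logistic forecaster with NUTS.

    Targets must sit exactly on the 9-level mood scale; they are mapped to
    category indices 1..K internally and back to mood levels on
    prediction.  All K = 9 categories are always modeled, even when the
    training data occupy only a few levels.
    """
    mcmc = mcmc or McmcConfig()
    logp_grad, dim, layout, init, ctx = _ordinal_target(data)
    patients = ctx["patients"]
    y = ctx["y_sorted"]
    j_count = len(patients)
    p = len(data.feature_names)
    n_cut = len(MOOD_LEVELS) - 1
    mu_beta_scale = ctx["mu_beta_scale"]
    tau_beta_scale = ctx["tau_beta_scale"]
    mu_cut_loc = ctx["mu_cut_loc"]
    mu_cut_scale = ctx["mu_cut_scale"]

    result = nuts_sample(logp_grad, dim, mcmc, initial=init)
    flat = result.flat
    d_count = len(flat)

    mu_beta = flat[:, layout["mu_beta"]]
    tau_beta = np.exp(flat[:, layout["log_tau_beta"]])
    mu_g = flat[:, layout["mu_g"]]
    tau_g = np.exp(flat[:, layout["log_tau_g"]])
    b_raw = flat[:, layout["b_raw"]].reshape(d_count, j_count, p)
    g_raw = flat[:, layout["g_raw"]].reshape(d_count, j_count, n_cut)
    g_unc = mu_g[:, None, :] + tau_g[:, None, :] * g_raw
    draws = {
        "mu_beta": mu_beta,
        "tau_beta": tau_beta,
        "mu_c": _cutpoints_from_unconstrained(mu_g),
        "tau_c": tau_g,
        "beta": mu_beta[:, None, :] + tau_beta[:, None, :] * b_raw,
        "cutpoints": _cutpoints_from_unconstrained(g_unc),
    }

    diagnostics, warnings = _diagnose(result.draws, layout, ["mu_beta", "mu_g"])
    diagnostics["divergences"] = result.divergences
    diagnostics["mean_accept"] = result.mean_accept
    priors = {
        "mu_beta": ["normal", 0.0, [float(s) for s in mu_beta_scale]],
        "tau_beta": ["half_normal", [float(s) for s in tau_beta_scale]],
        "mu_g": ["normal", mu_cut_loc.tolist(), mu_cut_scale.tolist()],
        "tau_g": ["half_normal", _TAU_CUT_SCALE],
    }
    return HierOrdinalPosterior(
        draws=draws,
        patients=patients,
        feature_names=list(data.feature_names),
        levels=MOOD_LEVELS.copy(),
        level_range=(float(np.min(y)), float(np.max(y))),
        config=mcmc,
        priors=priors,
        diagnostics=diagnostics,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------


@dataclass
class PredictiveSummary:
    """Posterior-predictive summary for one feature vector."""

    mean: float
    sd: float
    lower: float  # central 95% interval
    upper: float
    category_probs: dict[float, float] | None = None  # ordinal only


def _linear_mean_draws(posterior: HierLinearPosterior, x, pos, rng):
    d = posterior.draws
    if pos is not None:
        return d["alpha"][:, pos] + d["beta"][:, pos, :] @ x
    # cold start: fresh individual parameters from the population per draw
    n_draws = posterior.n_draws
    eps_a = rng.standard_normal(n_draws)
    eps_b = rng.standard_normal((n_draws, len(x)))
    alpha = d["mu_alpha"] + d["tau_alpha"] * eps_a
    beta = d["mu_beta"] + d["tau_beta"] * eps_b
    return alpha + beta @ x


def _fold_probs(probs: np.ndarray, levels: np.ndarray, level_range) -> np.ndarray:
    """Censor predictive mass to the training level range.

    Mass on categories below (above) the smallest (largest) level observed
    in training is accumulated onto that boundary level, so predictions
    and their uncertainties can never leave the range of the training
    data.
    """
    lo = int(np.searchsorted(levels, level_range[0]))
    hi = int(np.searchsorted(levels, level_range[1]))
    out = probs.copy()
    if lo > 0:
        out[..., lo] += out[..., :lo].sum(axis=-1)
        out[..., :lo] = 0.0
    if hi < len(levels) - 1:
        out[..., hi] += out[..., hi + 1 :].sum(axis=-1)
        out[..., hi + 1 :] = 0.0
    return out


def _ordinal_probs(posterior: HierOrdinalPosterior, x, pos, rng, fold=True, n_draws=None):
    d = posterior.draws
    take = slice(None)
    if n_draws is not None and n_draws < posterior.n_draws:
        take = np.linspace(0, posterior.n_draws - 1, n_draws).astype(int)
    if pos is not None:
        z = d["beta"][take, pos, :] @ x
        cuts = d["cutpoints"][take, pos, :]
    else:
        beta = d["mu_beta"][take]
        beta = beta + d["tau_beta"][take] * rng.standard_normal(beta.shape)
        z = np.einsum("dp,p->d", beta, x)
        # population-typical cutpoints per draw (ordered by construction)
        cuts = d["mu_c"][take]
    probs = ordered_logistic_pmf(z, cuts).mean(axis=0)
    if fold:
        probs = _fold_probs(probs, posterior.levels, posterior.level_range)
    return probs


def predict(
    posterior: HierLinearPosterior | HierOrdinalPosterior,
    features: np.ndarray,
    patient_id: str | None = None,
    n_draws: int | None = None,
    seed: int = 0,
) -> PredictiveSummary:
    """Posterior-predictive summary for one feature vector.

    For a patient seen in training the patient's own parameter draws are
    used; for an unseen (or ``None``) patient, individual parameters are
    drawn afresh from the fitted population distributions per retained
    draw (the cold-start contract).  The ordinal point prediction is the
    probability-weighted mean of the level values; ordinal intervals are
    quantiles of the predictive level distribution and therefore always
    land on levels inside the training range.
    """
    x = np.asarray(features, dtype=float)
    if x.shape != (len(posterior.feature_names),):
        raise ValidationError(
            f"feature vector must have length {len(posterior.feature_names)}"
        )
    rng = np.random.default_rng(seed)
    pos = posterior.patient_pos(patient_id) if patient_id is not None else None

    if isinstance(posterior, HierLinearPosterior):
        means = _linear_mean_draws(posterior, x, pos, rng)
        sigma = posterior.draws["sigma"]
        if n_draws is not None and n_draws < len(means):
            keep = rng.choice(len(means), size=n_draws, replace=False)
            means, sigma = means[keep], sigma[keep]
        y_rep = means + sigma * rng.standard_normal(len(means))
        lo, hi = np.quantile(y_rep, [0.025, 0.975])
        return PredictiveSummary(
            mean=float(np.mean(means)),
            sd=float(np.sqrt(np.var(means) + np.mean(sigma**2))),
            lower=float(lo),
            upper=float(hi),
        )

    probs = _ordinal_probs(posterior, x, pos, rng, n_draws=n_draws)
    levels = posterior.levels
    mean = float(probs @ levels)
    sd = float(np.sqrt(max(probs @ levels**2 - mean**2, 0.0)))
    cdf = np.cumsum(probs)
    lower = float(levels[np.searchsorted(cdf, 0.025)])
    upper = float(levels[np.searchsorted(cdf, 0.975)])
    return PredictiveSummary(
        mean=mean,
        sd=sd,
        lower=lower,
        upper=upper,
        category_probs={float(lv): float(pr) for lv, pr in zip(levels, probs)},
    )


def point_predictions(
    posterior: HierLinearPosterior | HierOrdinalPosterior,
    data: ForecastDataset,
    max_draws: int = 400,
) -> np.ndarray:
    """Vectorized posterior-mean predictions for every example in ``data``.

    Unseen patients fall back to the population mean parameters (the
    expectation of the cold-start draw).  For the ordinal model the point
    prediction is the expected level under the (range-censored) predictive
    pmf, averaged over up to ``max_draws`` posterior draws.
    """
    pos = np.array(
        [
            -1 if (q := posterior.patient_pos(data.patient_ids[g])) is None else q
            for g in range(len(data.patient_ids))
        ]
    )
    ex_pos = pos[data.patient_index]  # compact position or -1 per example
    seen = ex_pos >= 0
    X = data.X
    d = posterior.draws

    if isinstance(posterior, HierLinearPosterior):
        mean_alpha = d["alpha"].mean(axis=0)
        mean_beta = d["beta"].mean(axis=0)
        out = np.empty(data.n_examples)
        if seen.any():
            out[seen] = mean_alpha[ex_pos[seen]] + np.einsum(
                "np,np->n", X[seen], mean_beta[ex_pos[seen]]
            )
        if (~seen).any():
            out[~seen] = d["mu_alpha"].mean() + X[~seen] @ d["mu_beta"].mean(axis=0)
        return out

    n_draws = posterior.n_draws
    take = (
        np.linspace(0, n_draws - 1, max_draws).astype(int)
        if n_draws > max_draws
        else np.arange(n_draws)
    )
    probs = np.zeros((data.n_examples, len(posterior.levels)))
    beta = d["beta"][take]
    cuts = d["cutpoints"][take]
    mu_beta = d["mu_beta"][take]
    mu_c = d["mu_c"][take]
    for t in range(len(take)):
        z = np.empty(data.n_examples)
        c_rows = np.empty((data.n_examples, cuts.shape[-1]))
        if seen.any():
            z[seen] = np.einsum("np,np->n", X[seen], beta[t, ex_pos[seen]])
            c_rows[seen] = cuts[t, ex_pos[seen]]
        if (~seen).any():
            z[~seen] = X[~seen] @ mu_beta[t]
            c_rows[~seen] = mu_c[t]
        probs += ordered_logistic_pmf(z, c_rows)
    probs /= len(take)
    probs = _fold_probs(probs, posterior.levels, posterior.level_range)
    return probs @ posterior.levels


# ---------------------------------------------------------------------------
# posterior predictive replication
# ---------------------------------------------------------------------------


@dataclass
class ReplicationReport:
    """Tail check of replicated versus observed mood.

    ``ratio_*`` is replicated tail mass as a percentage of the observed
    tail mass; ``None`` when the observed tail is empty (the check is not
    applicable, never a division by zero).
    """

    observed_below: float
    observed_above: float
    replicated_below: float
    replicated_above: float
    ratio_below: float | None
    ratio_above: float | None
    n_examples: int
    n_draws: int


def posterior_predictive_replicate(
    posterior: HierLinearPosterior | HierOrdinalPosterior,
    data: ForecastDataset,
    n_draws: int = 500,
    seed: int = 0,
    return_draws: bool = False,
):
    """Replicate targets from the fitted model and report tail coverage.

    One replicated target per (example, retained draw) for up to
    ``n_draws`` equally spaced retained draws; tails are the strict bands
    mood < -0.75 (depression) and mood > 0.75 (mania).
    """
    if list(posterior.feature_names) != list(data.feature_names):
        raise ValidationError("posterior and dataset feature layouts differ")
    rng = np.random.default_rng(seed)
    total = posterior.n_draws
    take = (
        np.linspace(0, total - 1, n_draws).astype(int) if total > n_draws else np.arange(total)
    )
    pos = np.array(
        [
            -1 if (q := posterior.patient_pos(data.patient_ids[g])) is None else q
            for g in range(len(data.patient_ids))
        ]
    )
    ex_pos = pos[data.patient_index]
    if np.any(ex_pos < 0):
        raise ValidationError("replication requires every patient to be in the posterior")
    X = data.X
    d = posterior.draws

    if isinstance(posterior, HierLinearPosterior):
        alpha = d["alpha"][take][:, ex_pos]
        beta = d["beta"][take]
        mean = alpha + np.einsum("np,dnp->dn", X, beta[:, ex_pos, :])
        rep = mean + d["sigma"][take][:, None] * rng.standard_normal(mean.shape)
    else:
        rep = np.empty((len(take), data.n_examples))
        for t in range(len(take)):
            z = np.einsum("np,np->n", X, d["beta"][take[t], ex_pos])
            pmf = ordered_logistic_pmf(z, d["cutpoints"][take[t], ex_pos])
            cdf = np.cumsum(pmf, axis=1)
            u = rng.random((data.n_examples, 1))
            idx = (u > cdf).sum(axis=1)
            rep[t] = posterior.levels[np.minimum(idx, len(posterior.levels) - 1)]

    obs_below = float(np.mean(data.y < -0.75))  # strict euthymia-band edges
    obs_above = float(np.mean(data.y > 0.75))
    rep_below = float(np.mean(rep < -0.75))
    rep_above = float(np.mean(rep > 0.75))
    report = ReplicationReport(
        observed_below=obs_below,
        observed_above=obs_above,
        replicated_below=rep_below,
        replicated_above=rep_above,
        ratio_below=None if obs_below == 0 else 100.0 * rep_below / obs_below,
        ratio_above=None if obs_above == 0 else 100.0 * rep_above / obs_above,
        n_examples=data.n_examples,
        n_draws=len(take),
    )
    return (report, rep) if return_draws else report


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def save_posterior(posterior, directory: str) -> None:
    """Serialize a fitted posterior to a directory.

    Draw arrays go to ``draws.npz``; everything needed to reconstruct the
    object (patient map, feature order, MCMC config, the priors actually
    used, diagnostics) to ``meta.json``.
    """
    import dataclasses
    import json
    import os

    os.makedirs(directory, exist_ok=True)
    np.savez(os.path.join(directory, "draws.npz"), **posterior.draws)
    meta = {
        "kind": posterior.kind,
        "patients": posterior.patients,
        "feature_names": posterior.feature_names,
        "config": dataclasses.asdict(posterior.config),
        "priors": posterior.priors,
        "diagnostics": posterior.diagnostics,
        "warnings": posterior.warnings,
    }
    if isinstance(posterior, HierOrdinalPosterior):
        meta["levels"] = posterior.levels.tolist()
        meta["level_range"] = list(posterior.level_range)
    with open(os.path.join(directory, "meta.json"), "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2)


def load_posterior(directory: str):
    """Load a posterior saved by :func:`save_posterior`."""
    import json
    import os

    with open(os.path.join(directory, "meta.json"), encoding="utf-8") as fh:
        meta = json.load(fh)
    with np.load(os.path.join(directory, "draws.npz")) as npz:
        draws = {k: npz[k] for k in npz.files}
    config = McmcConfig(**meta["config"])
    common = dict(
        draws=draws,
        patients=meta["patients"],
        feature_names=meta["feature_names"],
        config=config,
        priors=meta["priors"],
        diagnostics=meta["diagnostics"],
        warnings=meta["warnings"],
    )
    if meta["kind"] == "hier_linear":
        return HierLinearPosterior(**common)
    return HierOrdinalPosterior(
        levels=np.asarray(meta["levels"]),
        level_range=tuple(meta["level_range"]),
        **common,
    )
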