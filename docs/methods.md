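# Methods

## The forecasting problem

Patients with bipolar disorder answer a ten-item smartphone questionnaire
once per day (activity, alcohol, anxiety, irritability, cognitive
difficulty, medicine adherence, mixed mood, mood, sleep, stress).  Mood is
recorded on a 9-level ordinal scale {-3, -2, -1, -0.5, 0, 0.5, 1, 2, 3},
denser near zero where patients spend most of their time (euthymia).  The
task is *forecasting*: predict the mood `h` days ahead from a window of the
`w` most recent fully observed days.  Missing days are genuinely missing —
nothing is imputed, and a window is only formed when all `w` history days
and the target day were reported.

## Preprocessing

* **Medicine** (categorical: taken / not taken / taken with changes)
  becomes two exclusive binaries, `medicine_omitted` and `medicine_changed`.
* **Sleep** is centered on the patient's own mean and split into a
  non-positive and a non-negative component (`sleep_negative`,
  `sleep_positive`), since shortened and lengthened sleep plausibly relate
  to mood differently.  The patient mean is computed over that patient's
  observed records.  We use the full-series mean everywhere: it is a
  per-patient constant that does not involve the target variable, so the
  leakage it could introduce into temporal cross-validation is negligible
  next to the convenience of a single fixed design matrix; callers that
  want strict training-period centering can pass per-patient means to
  `build_windows`.
* **Normalisation**: every predictor is mapped to [0, 1] by its allowed
  range.  The open-ended alcohol item ("10+") is capped at 10.  The split
  sleep components use a fixed +/-12 h range so the transform stays
  data-independent; deviations beyond that (possible only for extreme
  sleep patterns) are clamped.  The *target* mood stays on the raw -3..3
  scale, so reported RMSE is in raw mood units.

Per day the 12 predictors are ordered
`[mood, activity, alcohol, anxiety, irritable, cognitive_difficulty,
medicine_omitted, medicine_changed, mixed_mood, sleep_negative,
sleep_positive, stress]`, and a window stacks days oldest -> newest
(`item@lag` labels, lag 0 = the anchor day).

## The hierarchical models

For patient j and example i with feature vector x_ji (length 12w):

**Linear**: y_ji ~ Normal(alpha_j + beta_j' x_ji, sigma), with
alpha_j ~ Normal(mu_alpha, tau_alpha) and beta_j ~ Normal(mu_beta,
tau_beta) elementwise.  Partial pooling interpolates between one pooled
regression (tau -> 0) and independent per-patient regressions
(tau -> inf), and the population distributions supply parameters for
patients never seen in training (cold start).

**Ordinal**: the mood level is treated as an incomplete measurement of a
latent score z_ji = beta_j' x_ji; y_ji ~ OrderedLogistic(z_ji, c_j) with
K = 9 categories and per-patient ordered cutpoints c_j partially pooled
across patients.  The model has no intercept (location is absorbed by the
cutpoints).  Its point forecast is the probability-weighted mean of the
level values, so it is scored with the same R^2/RMSE as the linear models.

### Priors

All priors live on the normalized-feature scale and encode one substantive
expectation: lagged mood is the dominant predictor.

| parameter | prior |
| --- | --- |
| mu_alpha | Normal(0, 1) |
| mu_beta (mood lags) | Normal(0, 1) |
| mu_beta (other items) | Normal(0, 0.25) |
| tau_beta (mood lags) | Half-Normal(1) |
| tau_alpha, tau_beta (others), sigma | Half-Normal(0.25) |
| cutpoints: first / log-increments (population) | Normal(-3, 2) / Normal(-0.5, 1) |
| cutpoint population scales | Half-Normal(0.25) |

### Cutpoint ordering

Cutpoints are parameterized as a first cutpoint plus exponentiated
increments; the patient-level hierarchy (population mean and scale,
non-centered residuals) lives on that unconstrained scale.  Every draw
therefore satisfies the ordering constraint exactly, for the population
cutpoints and every patient, with no rejection or sorting step.  The cost
is that "Normal population distribution of cutpoints" holds on the
transformed scale rather than the cutpoint scale — an intentional design
choice for exact constraint satisfaction.

### Sampling

Both models are sampled with a No-U-Turn sampler written in this package
(`moodcast.sampler`): slice-variant NUTS with dual-averaging step-size
adaptation (target acceptance 0.8), diagonal mass-matrix estimation in
doubling warm-up windows, and a divergence guard at a 1000-nat drop of the
joint density.  Log densities and analytic gradients are evaluated by
numba kernels and are verified against finite differences in the test
suite; the sampler itself is validated on anisotropic Gaussians and via
parameter-recovery studies.  Individual-level parameters use the
non-centered parameterization throughout.  The default budget is 4 chains
x 5,000 iterations with the first half as warm-up (10,000 retained
draws); the test suite and acceptance script use reduced budgets
(2-4 chains x 400-1,000 iterations), which parameter-recovery calibration
shows is adequate at their problem sizes.  Split-R-hat and bulk ESS are
computed for population parameters (via ArviZ); R-hat > 1.05 is recorded
as a warning on the posterior, never raised.

### Prediction

For a training patient, predictions use that patient's parameter draws.
For an unseen patient, fresh individual parameters are drawn from the
fitted population distributions per retained draw.  Linear predictive
intervals include observation noise.  Ordinal predictive mass outside the
range of training levels is folded onto the nearest observed boundary
level (a censoring view of "the model cannot predict outside its training
range"), so ordinal point predictions and interval endpoints are
guaranteed to stay within the observed training range; posterior
predictive *replication* uses the unfolded pmf, since there the model's
own generative behavior is the object under study.

## Baselines

`last_observed` repeats the newest windowed mood; `pooled_mean` /
`separate_mean` predict training-target means; `pooled_ridge` /
`separate_ridge` (lambda = 1) and `pooled_gbt` / `separate_gbt`
(100 trees, depth 3, learning rate 0.1, via scikit-learn and XGBoost)
regress the target on the flattened window.  Separate variants refuse
unseen patients; the CV engine excludes and counts those pairs.

## Cross-validation

Two schemes, both leakage-guarded by construction and by explicit
assertions on every plan:

* **leave-all-out**: each patient's timeline is cut into T consecutive
  partitions (default one week), anchored at that patient's first record
  (the study population enrolled over years, so calendar alignment would
  make fold sizes wildly uneven).  An example belongs to the fold of its
  *target* date.  Fold k tests partition k pooled over patients and trains
  on all earlier partitions; the first partition is never tested.
* **leave-one-out**: per held-out patient, their first `train_period`
  days (default 14) pool with everyone else's data; their following
  `test_period` days (default 154) are tested.  Patients with no test
  examples are excluded and counted.

Metrics (predicted R^2 and RMSE) are computed once on the pooled test
predictions of all folds; R^2's reference mean is the pooled test-set
mean, so negative values mean "worse than predicting that mean".
Separate-kind models fit the held-out patient's training slice in
leave-one-out like any other patient; examples they cannot predict
(unseen patients) are excluded pairwise and reported rather than scored.

Window and horizon sweeps rebuild the window dataset per configuration
(missingness makes the datasets differ) and report the per-configuration
dataset size alongside the metrics.  The horizon sweep also reports each
model's mean absolute deviation of predictions from the training-target
mean: as the horizon grows the predictable AR signal decays and forecasts
regress toward the mean.

## Feature importance

Per patient and weight, t = posterior mean / posterior SD of the
individual-level weight; the table reports mean and SD over patients of
|t| per (item, lag), sorted descending.  Zero-SD (degenerate) weights
report not-applicable.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis relies on,
calibrated to the study's descriptive statistics: per-patient latent mood
is a stationary AR(1) around an individual baseline
(baseline ~ Normal(-0.14, 0.30), AR coefficient 0.7, innovation SD 0.27,
giving pooled observed mood mean ~ -0.14 and SD ~ 0.48); observed mood
snaps to the nearest of the 9 levels (midpoint ties toward zero);
covariates are same-day noisy monotone functions of latent mood (activity
up, anxiety/irritability/stress/cognitive difficulty/mixed mood down,
sleep shortening as mood climbs), so their lagged correlations with mood
arise through mood's own autocorrelation; medicine is categorical with
fixed probabilities 0.85/0.10/0.05; days drop out independently (MCAR) at
rate 1 - adherence with adherence defaulting to 0.828.

What it does *not* emulate: the heavy left skew of the clinical mood
distribution (a Gaussian latent gives ~10%/2-3% tail masses against the
study's 8.7%/1.7%), episode dynamics (persistent depressive or manic
phases beyond AR(1) decay), informative missingness (real adherence
likely drops when patients are unwell), clinician rating scales, and any
seasonality (none was found in the study).  Passing tests therefore
demonstrate the machinery and its statistical properties under the
assumed structure — not clinical performance.

## Problem sizes and numerical choices

Tests and the acceptance script run on deliberately small cohorts
(J = 6-20 patients, 33-61 days, w = 1) with reduced MCMC budgets; these
sizes are the package's chosen study conditions for desk-scale
verification and give hierarchical-linear leave-all-out R^2 around
0.4-0.6 on the calibrated cohorts.  The horizon analysis uses two-week CV
partitions and a near-homogeneous population so that fold sizes stay
comparable across horizons and regression-to-the-mean is measured against
a meaningful pooled mean (with strong patient baselines the deviation is
floored at the baseline spread).  Degenerate situations are reported, not
crashed on: zero test variance makes R^2 not-applicable (NaN), empty
observed tails make replication ratios not-applicable (None), empty fold
sides are dropped with a notice.

## Known limitations

* The sampler is single-threaded; chains run sequentially.
* Posterior containers hold dense per-patient draw arrays; at the full
  default budget with many patients and w = 4 they reach hundreds of MB.
* The ordinal model's cold-start prediction uses the population-typical
  cutpoints rather than integrating over cutpoint heterogeneity.
* MCAR missingness and nearest-level discretisation are simplifications;
  both are isolated behind `PopulationConfig` and `discretize_mood`.
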