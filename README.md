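# moodcast

Forecasting daily self-assessed mood in bipolar disorder from smartphone
questionnaires, with hierarchical Bayesian regression.

Patients with bipolar disorder report ten items once a day (mood on a
9-level ordinal scale {-3 … 3}, plus activity, alcohol, anxiety,
irritability, cognitive difficulty, medicine adherence, mixed mood, sleep
and stress).  Forecasting tomorrow's (or next week's) mood from a short
window of these self-assessments enables earlier intervention before
depressive or manic episodes build up.  The statistical difficulty is that
every patient is different but most contribute too little data for a
personal model — the classic partial-pooling setting.

`moodcast` is aimed at methods researchers in digital phenotyping and
computational psychiatry.  It provides:

* **Hierarchical Bayesian forecasters** — a linear model
  *y*ⱼᵢ ~ Normal(αⱼ + βⱼᵀ**x**ⱼᵢ, σ) and an ordered-logistic model
  *y*ⱼᵢ ~ OrderedLogistic(βⱼᵀ**x**ⱼᵢ, **c**ⱼ), with per-patient
  parameters drawn from population distributions
  (αⱼ ~ N(μ_α, τ_α), βⱼ ~ N(μ_β, τ_β), ordered cutpoints **c**ⱼ
  partially pooled).  Sampling is NUTS with a non-centered
  parameterization; the sampler ships with the package and is verified
  against finite differences, closed forms and parameter-recovery
  studies.  Unseen patients are handled by drawing fresh individual
  parameters from the population (cold start).
* **The preprocessing pipeline**: categorical medicine → two exclusive
  binaries, sleep → negative/positive deviation from the patient's mean,
  min–max normalisation, and strict windowing (w fully observed history
  days, target h days ahead, no imputation).
* **Two time-series cross-validation schemes** (consecutive pooled
  partitions; held-out patient with a two-week personal training slice),
  leakage-guarded, with predicted R²/RMSE pooled across folds, window and
  horizon sweeps, |t|-statistic feature importance and posterior-predictive
  tail checks.
* **Baselines**: last-observed, pooled/separate means, ridge and
  gradient-boosted trees.
* **A seeded synthetic cohort generator** calibrated to the descriptive
  statistics of a real monitoring cohort (pooled mood mean ≈ −0.14,
  SD ≈ 0.48, adherence ≈ 83%, positive week-scale mood autocorrelation),
  so the whole pipeline is testable without clinical data.

## Worked example

```python
from moodcast import (PopulationConfig, generate_population, summarize_population,
                      build_windows, fit_hier_linear, McmcConfig, predict,
                      ModelSpec, make_leave_all_out_splits, run_cv)

series = generate_population(PopulationConfig(n_patients=15, n_days=80, seed=7))
s = summarize_population(series)
print(f"cohort: {s.n_records} records, mood mean {s.mood_mean:.3f}, "
      f"SD {s.mood_sd:.3f}, adherence {s.adherence:.1%}")

data = build_windows(series, w=1, h=1)          # 1-day history, 1-day forecast
plan = make_leave_all_out_splits(data, T=8, partition_length=7)
mcmc = McmcConfig(chains=2, iterations=500, seed=7)
specs = [ModelSpec("pooled mean", "pooled_mean"),
         ModelSpec("last observed", "last_observed"),
         ModelSpec("pooled ridge", "pooled_ridge"),
         ModelSpec("hierarchical linear", "hier_linear", mcmc=mcmc)]
print(run_cv(specs, plan, data).table[["model", "r2", "rmse", "n_test", "n_folds"]]
      .round(3).to_string(index=False))

post = fit_hier_linear(data, mcmc)
sm = predict(post, data.X[0], patient_id="P001", seed=0)
print(f"one-day forecast for P001: mean {sm.mean:.2f}, "
      f"95% interval [{sm.lower:.2f}, {sm.upper:.2f}]")
```

prints

```
cohort: 1007 records, mood mean -0.116, SD 0.457, adherence 84.6%
              model     r2  rmse  n_test  n_folds
        pooled mean -0.012 0.471     521        7
      last observed  0.454 0.346     521        7
       pooled ridge  0.436 0.352     521        7
hierarchical linear  0.493 0.334     521        7
one-day forecast for P001: mean -0.45, 95% interval [-1.07, 0.16]
```

Reading the table: the pooled mean explains no variance (R² ≈ 0) and sets
the reference; repeating the last observed mood is already a strong naive
forecaster because mood is autocorrelated; the hierarchical model beats
both by pooling the population signal while keeping per-patient intercepts
and weights.  RMSE is in raw mood units on the −3..3 scale.  The forecast
interval is a posterior-predictive 95% band for that patient-day.

A command-line interface mirrors the library
(`moodcast simulate | windows | fit | cv | sweep-w | sweep-h | check |
importance`); every run writes its resolved configuration and seed next to
its artifacts, so any output is reproducible from the directory alone.

```bash
moodcast simulate --out cohort.csv --patients 20 --days 90 --seed 1
moodcast cv --input cohort.csv --out cvres --scheme leave_all_out \
        --folds 6 -w 1 --horizon 1 --chains 2 --iterations 500 --seed 1
```

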