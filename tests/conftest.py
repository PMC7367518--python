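import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from moodcast.items import ITEM_COLUMNS, MOOD_LEVELS
from moodcast.preprocessing import ForecastDataset
from moodcast.records import PatientSeries
from moodcast.sampler import McmcConfig

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def fast_mcmc():
    """Small but adequate MCMC budget for unit tests."""
    return McmcConfig(chains=2, iterations=400, seed=0)


def make_series(
    patient_id: str,
    days,
    mood=None,
    sleep=None,
    medicine="taken",
    start="2020-01-01",
) -> PatientSeries:
    """A patient series observed on the given 1-based day numbers."""
    days = list(days)
    n = len(days)
    if mood is None:
        mood = [0.0] * n
    if sleep is None:
        sleep = [7.0] * n
    start_ts = pd.Timestamp(start)
    df = pd.DataFrame(
        {
            "date": [start_ts + pd.Timedelta(days=d - 1) for d in days],
            "activity": 0,
            "alcohol": 0,
            "anxiety": 0,
            "irritable": 0,
            "cognitive_difficulty": 0,
            "medicine": medicine,
            "mixed_mood": 0,
            "mood": mood,
            "sleep": sleep,
            "stress": 0,
        }
    )[["date"] + ITEM_COLUMNS]
    return PatientSeries(patient_id=patient_id, data=df)


def make_linear_dataset(
    rng,
    j_count=10,
    per_patient=30,
    mu_beta=None,
    tau_alpha=0.3,
    tau_beta=0.05,
    sigma=0.3,
    mu_alpha=0.0,
):
    """Generate a windowed dataset directly from the hierarchical linear
    model (w=1, 12 predictors), for parameter-recovery style checks."""
    p = 12
    if mu_beta is None:
        mu_beta = np.zeros(p)
        mu_beta[0] = 0.8
    n = j_count * per_patient
    X = rng.random((n, p))
    pidx = np.repeat(np.arange(j_count), per_patient)
    alpha = mu_alpha + tau_alpha * rng.standard_normal(j_count)
    beta = mu_beta + tau_beta * rng.standard_normal((j_count, p))
    y = alpha[pidx] + np.einsum("np,np->n", X, beta[pidx]) + sigma * rng.standard_normal(n)
    dates = np.tile(np.arange(per_patient), j_count).astype("datetime64[D]")
    data = ForecastDataset(
        X=X,
        y=y,
        patient_index=pidx,
        anchor_dates=dates,
        patient_ids=[f"P{j:02d}" for j in range(j_count)],
        w=1,
        h=1,
    )
    truth = {"mu_alpha": mu_alpha, "mu_beta": np.asarray(mu_beta), "sigma": sigma,
             "alpha": alpha, "beta": beta}
    return data, truth


def make_ordinal_dataset(rng, j_count=6, per_patient=40, levels=None, beta0=1.5):
    """Ordinal targets from a latent score + logistic noise, snapped to the
    given mood levels via even quantile cutpoints."""
    p = 12
    levels = MOOD_LEVELS if levels is None else np.asarray(levels, dtype=float)
    n = j_count * per_patient
    X = rng.random((n, p))
    pidx = np.repeat(np.arange(j_count), per_patient)
    z = beta0 * X[:, 0] + rng.logistic(size=n)
    qs = np.quantile(z, np.linspace(0, 1, len(levels) + 1)[1:-1])
    cat = np.searchsorted(qs, z)
    y = levels[cat]
    dates = np.tile(np.arange(per_patient), j_count).astype("datetime64[D]")
    data = ForecastDataset(
        X=X,
        y=y,
        patient_index=pidx,
        anchor_dates=dates,
        patient_ids=[f"P{j:02d}" for j in range(j_count)],
        w=1,
        h=1,
    )
    return data
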