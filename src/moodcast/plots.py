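"""Figure helpers for sweep results and example forecasts."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd


def plot_metric_sweep(table: pd.DataFrame, x: str, path: str, metric: str = "rmse") -> None:
    """One line per model: ``metric`` against window size or horizon."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for model, grp in table.groupby("model"):
        grp = grp.sort_values(x)
        ax.plot(grp[x], grp[metric], marker="o", label=model)
    ax.set_xlabel({"w": "window size (days)", "h": "forecast horizon (days)"}.get(x, x))
    ax.set_ylabel(metric.upper() if metric == "rmse" else metric)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_forecast_fan(dates, observed, mean, lower, upper, path: str) -> None:
    """An example mood forecast with its central 95% band."""
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(dates, observed, "k.-", label="observed mood")
    ax.plot(dates, mean, "C0.-", label="forecast")
    ax.fill_between(dates, lower, upper, color="C0", alpha=0.25, label="95% interval")
    ax.set_ylim(-3.2, 3.2)
    ax.set_ylabel("mood")
    ax.legend(fontsize=8)
    fig.autofmt_xdate()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
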