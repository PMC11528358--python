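"""Figure helpers for experiment reports (matplotlib)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_age_cost", "plot_protective_effects"]


def plot_age_cost(frame: pd.DataFrame, ax=None, sample: int = 2000, seed: int = 0):
    """Accumulated infection cost against age with a linear trend line.

    ``frame`` is an analysis frame (one parameterization); points are a
    random subsample of individual simulation outcomes.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    sub = frame.sample(min(sample, len(frame)), random_state=seed)
    ax.scatter(sub["age"], sub["cost"], s=6, alpha=0.25, color="tab:blue")
    b, a = np.polyfit(frame["age"], frame["cost"], 1)
    xs = np.array(sorted(frame["age"].unique()))
    ax.plot(xs, a + b * xs, color="tab:red", lw=2)
    ax.set_xlabel("age (years)")
    ax.set_ylabel("accumulated infection cost")
    return ax


def plot_protective_effects(report: pd.DataFrame, ax=None):
    """Bar chart of the protective effect per parameterization (negative
    bars mean age-related sociality differences buffer infection cost)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(max(5, 0.5 * len(report)), 4))
    ax.bar(report["param_id"], report["protective_effect"], color="tab:purple")
    ax.axhline(0, color="k", lw=0.8)
    ax.set_ylabel("protective effect (model 1 - model 2 age estimate)")
    ax.tick_params(axis="x", rotation=90)
    return ax
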