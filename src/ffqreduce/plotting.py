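"""Figures for sweep results: per-goal bar panels and aggregate trend lines."""
from __future__ import annotations

import numpy as np
import pandas as pd

from .experiments import ExperimentResult, aggregate_by_active_count

__all__ = ["plot_error_by_goal", "plot_mean_error_trends"]

_ARM_COLORS = {"random": "#d4a017", "static": "#d16a8a", "personalised": "#4878b0"}


def plot_error_by_goal(result: ExperimentResult | pd.DataFrame, n_features: int,
                       n_active_values=None):
    """One row of bar panels per activated-set size, one column per arm.

    Bars show the mean portions/day error per goal at the given feature
    count, averaged over seeds and combinations of that size.
    """
    import matplotlib.pyplot as plt

    df = result.records if isinstance(result, ExperimentResult) else result
    df = df[(df["status"] == "ok") & (df["n_features"] == n_features)]
    if df.empty:
        raise ValueError(f"no records at n_features={n_features}")
    arms = [a for a in _ARM_COLORS if a in df["arm"].unique()]
    sizes = sorted(df["n_active"].unique())
    if n_active_values is not None:
        sizes = [s for s in sizes if s in set(n_active_values)]
    fig, axes = plt.subplots(
        len(sizes), len(arms),
        figsize=(4.0 * len(arms), 2.4 * len(sizes)),
        squeeze=False, sharey="row",
    )
    for i, size in enumerate(sizes):
        for j, arm in enumerate(arms):
            ax = axes[i][j]
            sub = df[(df["n_active"] == size) & (df["arm"] == arm)]
            means = sub.groupby("goal")["error"].mean().sort_index()
            ax.bar(range(len(means)), means.values, color=_ARM_COLORS[arm])
            ax.set_xticks(range(len(means)))
            ax.set_xticklabels(means.index, rotation=90, fontsize=6)
            if j == 0:
                ax.set_ylabel(f"{size} goals\nerror (portions/day)", fontsize=7)
            if i == 0:
                ax.set_title(arm)
    fig.suptitle(f"Per-goal test error, {n_features} questions shown")
    fig.tight_layout()
    return fig


def plot_mean_error_trends(result: ExperimentResult | pd.DataFrame):
    """Mean error vs number of activated goals, one panel per arm.

    Lines within a panel correspond to the number of selected questions.
    """
    import matplotlib.pyplot as plt

    agg = aggregate_by_active_count(result)
    arms = [a for a in _ARM_COLORS if a in agg["arm"].unique()]
    fig, axes = plt.subplots(1, len(arms), figsize=(4.0 * len(arms), 3.2),
                             squeeze=False, sharey=True)
    for j, arm in enumerate(arms):
        ax = axes[0][j]
        sub = agg[agg["arm"] == arm]
        for n in sorted(sub["n_features"].unique()):
            line = sub[sub["n_features"] == n].sort_values("n_active")
            ax.plot(line["n_active"], line["error"], marker="o",
                    label=f"{n} questions")
        ax.set_title(arm)
        ax.set_xlabel("activated goals")
        if j == 0:
            ax.set_ylabel("mean error (portions/day)")
        ax.legend(fontsize=7)
    fig.tight_layout()
    return fig
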