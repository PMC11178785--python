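"""Plots: SuperPlot-style group scatter, worm plots, and log-log MSD panels."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .io import Cohort
from .metrics import msd_all_pairs

__all__ = ["superplot", "worm_plot", "msd_loglog_plot"]


def superplot(metrics: pd.DataFrame, metric: str = "net_displacement_um", ax=None):
    """Cell-level scatter per group with replicate means overlaid as large
    circles and mean ± SEM of the replicate means as the error bar."""
    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * metrics["group"].nunique() + 1.5, 3.5))
    groups = sorted(metrics["group"].unique())
    rng = np.random.default_rng(0)
    for i, g in enumerate(groups):
        sub = metrics[metrics["group"] == g]
        x = i + rng.uniform(-0.18, 0.18, len(sub))
        ax.scatter(x, sub[metric], s=6, color="0.6", alpha=0.6, lw=0)
        reps = sub.groupby("replicate_id")[metric].mean()
        ax.scatter(np.full(len(reps), i), reps, s=55, facecolor="gold",
                   edgecolor="k", zorder=3)
        if len(reps) >= 2:
            m, sem = reps.mean(), reps.std(ddof=1) / np.sqrt(len(reps))
            ax.errorbar(i, m, yerr=sem, fmt="_", color="k", capsize=5, zorder=4)
    ax.set_xticks(range(len(groups)), groups)
    ax.set_ylabel(metric)
    return ax


def worm_plot(cohort: Cohort, max_tracks: int = 30, ax=None):
    """Trajectories translated to a common origin ("worm plot")."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    for tr in cohort.tracks[:max_tracks]:
        r = tr.positions
        r = r - r[0]
        ax.plot(r[:, 0], r[:, 1], lw=0.8, alpha=0.8)
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    ax.set_aspect("equal")
    return ax


def msd_loglog_plot(cohort: Cohort, max_lag_fraction: float = 0.25, ax=None):
    """Per-track MSD curves on log-log axes, restricted to the fit range."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3.5))
    for tr in cohort.tracks:
        c = msd_all_pairs(tr)
        keep = (c.lags <= max_lag_fraction * tr.duration) & (c.msd > 0)
        if keep.sum() >= 2:
            ax.loglog(c.lags[keep], c.msd[keep], lw=0.6, alpha=0.5)
    ax.set_xlabel("lag (s)")
    ax.set_ylabel("MSD (µm²)")
    return ax
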