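"""Replicate-aware cohort statistics (the "SuperPlot" convention).

The statistical unit throughout is the biological replicate, never the cell:
per-replicate means are computed over cells first, and group-level means,
SEMs and all significance tests operate on those replicate means.  Testing
at the cell level would treat hundreds of correlated cells as independent
observations and grossly inflate significance.

Group comparison is a one-way fixed-effects ANOVA on replicate means
followed by Tukey's HSD with a single pooled within-group variance, using
the studentized-range distribution for the adjusted p-values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import AnalysisConfig

__all__ = [
    "GroupSummary",
    "summarize_group",
    "replicate_means",
    "anova_tukey",
    "displacement_histogram",
]


@dataclass
class GroupSummary:
    group: str
    metric: str
    per_replicate_means: dict[str, float]
    grand_mean: float
    sem_of_replicate_means: float | None
    n_cells: int
    n_replicates: int
    fraction_non_motile: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_non_motile <= 1.0):
            raise ValueError("fraction_non_motile must be in [0, 1]")
        if self.n_replicates < 2 and self.sem_of_replicate_means is not None:
            raise ValueError("SEM is undefined with fewer than 2 replicates")


def replicate_means(metrics: pd.DataFrame, group: str, metric: str) -> dict[str, float]:
    """Per-replicate means of one metric within one group."""
    if metric not in metrics.columns:
        raise ValueError(f"unknown metric {metric!r}")
    sub = metrics[metrics["group"] == group]
    if sub.empty:
        raise ValueError(f"no tracks for group {group!r}")
    out = sub.groupby("replicate_id")[metric].mean()
    return {str(k): float(v) for k, v in out.items()}


def summarize_group(
    metrics: pd.DataFrame,
    group: str,
    metric: str = "net_displacement_um",
    config: AnalysisConfig | None = None,
) -> GroupSummary:
    """Replicate-aware summary of one metric in one group.

    ``metrics`` is the per-track table from
    :func:`pilitrack.metrics.compute_cohort_metrics`.
    """
    config = config or AnalysisConfig()
    reps = replicate_means(metrics, group, metric)
    vals = np.array(list(reps.values()))
    sub = metrics[metrics["group"] == group]
    frac_nm = float(
        (sub["net_displacement_um"] < config.non_motile_threshold).mean()
    )
    sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) >= 2 else None
    return GroupSummary(
        group=group, metric=metric, per_replicate_means=reps,
        grand_mean=float(vals.mean()), sem_of_replicate_means=sem,
        n_cells=int(len(sub)), n_replicates=int(len(vals)),
        fraction_non_motile=frac_nm,
    )


def anova_tukey(groups: dict[str, "np.ndarray | list[float]"]) -> dict:
    """One-way ANOVA + Tukey HSD on replicate means.

    Parameters
    ----------
    groups : mapping group label -> replicate means (the observations)

    Returns a dict with ``F``, ``df`` (between, within), ``p_anova`` and a
    ``comparisons`` DataFrame of all pairs with Tukey-adjusted p-values from
    the studentized-range distribution with the single pooled within-group
    variance.  Zero pooled variance makes p undefined (NaN, flagged).
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    data = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, v in data.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has < 2 replicate means")
    k = len(data)
    N = sum(len(v) for v in data.values())
    grand = np.concatenate(list(data.values())).mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in data.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in data.values())
    df_b, df_w = k - 1, N - k
    ms_between = ss_between / df_b
    ms_within = ss_within / df_w  # the single pooled variance
    degenerate = ms_within == 0.0
    if degenerate:
        F = np.inf if ms_between > 0 else 0.0
        p_anova = np.nan
    else:
        F = ms_between / ms_within
        p_anova = float(sps.f.sf(F, df_b, df_w))
    rows = []
    for (ga, va), (gb, vb) in itertools.combinations(data.items(), 2):
        diff = vb.mean() - va.mean()
        if degenerate:
            q = np.nan
            p_adj = np.nan
        else:
            se = np.sqrt(ms_within / 2.0 * (1.0 / len(va) + 1.0 / len(vb)))
            q = abs(diff) / se if se > 0 else np.nan
            p_adj = float(sps.studentized_range.sf(q, k, df_w))
        rows.append((ga, gb, diff, q, p_adj))
    comparisons = pd.DataFrame(
        rows, columns=["group_a", "group_b", "mean_diff", "q", "p_adj"]
    )
    return {
        "F": float(F), "df": (df_b, df_w), "p_anova": p_anova,
        "ms_within": float(ms_within), "degenerate": bool(degenerate),
        "comparisons": comparisons,
    }


def displacement_histogram(
    values: "np.ndarray | pd.Series | list[float]",
    bin_edges: "np.ndarray | list[float]",
    config: AnalysisConfig | None = None,
) -> np.ndarray:
    """Counts of displacements over half-open bins [a, b).

    A value exactly on an interior edge falls into the bin to its right;
    values >= the last edge or < the first are not counted.  When a config
    is supplied, the non-motile threshold must be one of the edges so the
    sub-threshold fraction read from the histogram agrees with the
    classifier.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    if config is not None and not np.any(np.isclose(edges, config.non_motile_threshold)):
        raise ValueError(
            f"non_motile_threshold {config.non_motile_threshold} must be a bin edge"
        )
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one value")
    idx = np.searchsorted(edges, v, side="right") - 1
    counts = np.zeros(len(edges) - 1, dtype=int)
    in_range = (idx >= 0) & (v < edges[-1])
    for i in idx[in_range]:
        counts[i] += 1
    return counts
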