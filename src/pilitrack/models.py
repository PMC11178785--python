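"""Model / Results interface over the analysis pipeline.

`MotilityModel` is built from a cohort of tracks (or a points table) and its
`fit()` returns a `MotilityResults` carrying per-track metrics, replicate-
aware group summaries, and the one-way ANOVA + Tukey HSD contrast on
replicate means.  `RetractionModel` does the same for pilus-length traces:
event detection, endpoint speed estimation, the replicate-aware mean speed,
and the speed-length correlation.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .io import Cohort, PilusTrace, cohort_from_dataframe
from .metrics import compute_cohort_metrics
from .retraction import (
    RetractionEvent,
    detect_retractions,
    events_to_dataframe,
    mean_retraction_speed,
    principal_event,
    speed_length_relation,
)
from .stats import GroupSummary, anova_tukey, replicate_means, summarize_group

__all__ = ["MotilityModel", "MotilityResults", "RetractionModel", "RetractionResults"]

_DEFAULT_METRICS = ["net_displacement_um", "persistence_ratio", "alpha"]


class MotilityModel:
    """Replicate-aware motility analysis of a cohort of 2-D tracks."""

    def __init__(self, cohort: Cohort, config: AnalysisConfig | None = None):
        self.cohort = cohort
        self.config = config or AnalysisConfig()

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        frame_interval: float | None = None,
        config: AnalysisConfig | None = None,
    ) -> "MotilityModel":
        """Build from a long-format points table
        (``track_id,replicate_id,group,t_s,x_um,y_um``)."""
        return cls(cohort_from_dataframe(df, frame_interval=frame_interval), config)

    def fit(self, metrics: Sequence[str] = _DEFAULT_METRICS) -> "MotilityResults":
        table = compute_cohort_metrics(self.cohort, self.config)
        summaries: dict[tuple[str, str], GroupSummary] = {}
        for group in self.cohort.groups:
            for metric in metrics:
                summaries[(group, metric)] = summarize_group(
                    table, group, metric, self.config
                )
        comparisons: dict[str, dict] = {}
        groups = self.cohort.groups
        if len(groups) >= 2:
            for metric in metrics:
                reps = {g: list(replicate_means(table, g, metric).values())
                        for g in groups}
                reps = {g: [v for v in vals if np.isfinite(v)] for g, vals in reps.items()}
                if all(len(v) >= 2 for v in reps.values()):
                    comparisons[metric] = anova_tukey(reps)
        return MotilityResults(self, table, summaries, comparisons)


class MotilityResults:
    def __init__(self, model, metrics, summaries, comparisons):
        self.model = model
        self.config = model.config
        self.metrics: pd.DataFrame = metrics
        self.summaries: dict[tuple[str, str], GroupSummary] = summaries
        self.comparisons: dict[str, dict] = comparisons

    def group_summary_table(self) -> pd.DataFrame:
        rows = []
        for (group, metric), s in self.summaries.items():
            rows.append((group, metric, s.grand_mean,
                         np.nan if s.sem_of_replicate_means is None
                         else s.sem_of_replicate_means,
                         s.n_replicates, s.n_cells, s.fraction_non_motile))
        return pd.DataFrame(rows, columns=[
            "group", "metric", "grand_mean", "sem", "n_replicates",
            "n_cells", "fraction_non_motile"])

    def comparisons_table(self) -> pd.DataFrame:
        frames = []
        for metric, res in self.comparisons.items():
            df = res["comparisons"].copy()
            df.insert(0, "metric", metric)
            df["F"] = res["F"]
            df["p_anova"] = res["p_anova"]
            frames.append(df)
        if not frames:
            return pd.DataFrame(columns=["metric", "group_a", "group_b",
                                         "mean_diff", "q", "p_adj", "F", "p_anova"])
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> str:
        lines = ["Motility analysis (replicate-aware)",
                 "=" * 45]
        lines.append(f"groups: {', '.join(self.model.cohort.groups)}; "
                     f"tracks: {len(self.model.cohort)}")
        lines.append(f"non-motile threshold: "
                     f"{self.config.non_motile_threshold} um")
        lines.append("")
        tbl = self.group_summary_table()
        with pd.option_context("display.width", 120):
            lines.append(tbl.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        comp = self.comparisons_table()
        if not comp.empty:
            lines.append("")
            lines.append("Pairwise contrasts (ANOVA + Tukey HSD on replicate means):")
            lines.append(comp.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)


class RetractionModel:
    """Retraction-event detection and speed estimation over pilus traces."""

    def __init__(
        self,
        traces: Sequence[PilusTrace],
        replicate_of: Mapping[str, str] | None = None,
        min_drop: float = 0.5,
        smoothing_window: int = 3,
        correlation: str = "pearson",
    ):
        self.traces = list(traces)
        self.replicate_of = dict(replicate_of or {})
        self.min_drop = min_drop
        self.smoothing_window = smoothing_window
        self.correlation = correlation

    def fit(self, principal_only: bool = True) -> "RetractionResults":
        """Detect events in every trace.  With ``principal_only`` each trace
        contributes its largest-drop event (one measurement per retraction
        movie); otherwise all detected events are kept."""
        events: list[RetractionEvent] = []
        for tr in self.traces:
            evs = detect_retractions(tr, self.min_drop, self.smoothing_window)
            if principal_only:
                ev = principal_event(evs)
                if ev is not None:
                    events.append(ev)
            else:
                events.extend(evs)
        by_rep: dict[str, list[RetractionEvent]] = {}
        for ev in events:
            rep = self.replicate_of.get(ev.cell_id, "rep1")
            by_rep.setdefault(rep, []).append(ev)
        grand = rep_means = sem = None
        if by_rep:
            grand, rep_means, sem = mean_retraction_speed(by_rep)
        corr = None
        if len(events) >= 3:
            try:
                corr = speed_length_relation(events, method=self.correlation)
            except ValueError:
                corr = None
        return RetractionResults(self, events, grand, rep_means or {}, sem, corr)


class RetractionResults:
    def __init__(self, model, events, mean_speed, replicate_mean_speeds, sem, correlation):
        self.model = model
        self.events: list[RetractionEvent] = events
        self.mean_speed: float | None = mean_speed
        self.replicate_mean_speeds: dict[str, float] = replicate_mean_speeds
        self.sem: float | None = sem
        #: (r, p, n) speed-vs-initial-length correlation, or None
        self.correlation = correlation

    def events_table(self) -> pd.DataFrame:
        return events_to_dataframe(self.events)

    def summary(self) -> str:
        lines = ["Pilus retraction kinetics", "=" * 45,
                 f"traces: {len(self.model.traces)}; events: {len(self.events)}"]
        if self.mean_speed is not None:
            sem = "undefined (single replicate)" if self.sem is None else f"{self.sem:.4g}"
            lines.append(f"mean retraction speed (grand mean of replicate means): "
                         f"{self.mean_speed:.4g} um/s, SEM {sem}")
            for rep, m in sorted(self.replicate_mean_speeds.items()):
                lines.append(f"  {rep}: {m:.4g} um/s")
        if self.correlation is not None:
            r, p, n = self.correlation
            lines.append(f"speed vs initial length ({self.model.correlation}): "
                         f"r={r:.4g}, p={p:.4g}, n={n}")
        return "\n".join(lines)
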