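"""Pilus-retraction kinetics from pilus-length time series.

A retraction event is a maximal stretch of decreasing pilus length.  Its
speed is the endpoint estimate |L_ini − L_final| / (t_final − t_ini) — the
length lost divided by the time taken, reported as a positive magnitude.
Measured single-pilus retraction speeds in Sulfolobus fall in the
0.3–2 µm/s range, with a wild-type single-pilus mean near 0.3 µm/s.

Detection runs on a moving-average-smoothed copy of the trace (window
default 3 frames) to keep localisation noise from fragmenting events, but
event endpoints are always read off the raw, unsmoothed trace.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import PilusTrace

__all__ = [
    "RetractionEvent",
    "detect_retractions",
    "principal_event",
    "retraction_speed",
    "speed_length_relation",
    "mean_retraction_speed",
    "events_to_dataframe",
]

EVENTS_COLUMNS = ["cell_id", "pilus_id", "t_ini_s", "t_final_s",
                  "L_ini_um", "L_final_um", "speed_um_per_s"]


@dataclass(frozen=True)
class RetractionEvent:
    cell_id: str
    pilus_id: str
    t_ini: float
    t_final: float
    L_ini: float
    L_final: float

    def __post_init__(self) -> None:
        if self.t_final <= self.t_ini:
            raise ValueError("t_final must exceed t_ini")
        if not (self.L_ini > self.L_final >= 0):
            raise ValueError("need L_ini > L_final >= 0")

    @property
    def drop(self) -> float:
        return self.L_ini - self.L_final

    @property
    def speed(self) -> float:
        return retraction_speed(self)


def retraction_speed(event: RetractionEvent) -> float:
    """Endpoint speed estimate |ΔL|/Δt (µm/s), as a positive magnitude."""
    dt = event.t_final - event.t_ini
    if dt <= 0:
        raise ValueError("event has zero duration")
    return (event.L_ini - event.L_final) / dt


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.astype(float)
    return (
        pd.Series(x).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


def detect_retractions(
    trace: PilusTrace,
    min_drop: float = 0.5,
    smoothing_window: int = 3,
) -> list[RetractionEvent]:
    """Find retraction events: maximal strictly-decreasing runs of the
    smoothed trace whose raw endpoint drop is at least ``min_drop`` µm.

    Plateaus split runs, so two linear drops separated by a constant
    stretch yield two events with boundaries at the plateau edges.
    Events never overlap and are returned in time order.
    """
    if len(trace) < 3:
        raise ValueError(
            f"trace ({trace.cell_id!r}, {trace.pilus_id!r}): needs >= 3 samples"
        )
    t = trace.times
    raw = trace.lengths
    smooth = _moving_average(raw, smoothing_window)
    decreasing = np.diff(smooth) < 0  # step i covers (i, i+1)
    events: list[RetractionEvent] = []
    i = 0
    n = len(decreasing)
    while i < n:
        if not decreasing[i]:
            i += 1
            continue
        j = i
        while j < n and decreasing[j]:
            j += 1
        a, b = i, j  # raw indices [a, b]
        if raw[a] - raw[b] >= min_drop:
            events.append(
                RetractionEvent(trace.cell_id, trace.pilus_id,
                                t_ini=float(t[a]), t_final=float(t[b]),
                                L_ini=float(raw[a]), L_final=float(raw[b]))
            )
        i = j
    return events


def principal_event(events: Sequence[RetractionEvent]) -> RetractionEvent | None:
    """The event with the largest length drop (the retraction proper, when a
    noisy trace fragments into several runs); None when no event was found."""
    if not events:
        return None
    return max(events, key=lambda e: e.drop)


def speed_length_relation(
    events: Sequence[RetractionEvent], method: str = "pearson"
) -> tuple[float, float, int]:
    """Correlation between retraction speed and initial pilus length.

    Returns (r, two-sided p, n).  Raises on n < 3; a zero-variance input
    makes the correlation undefined and is reported as such.
    """
    n = len(events)
    if n < 3:
        raise ValueError(f"need >= 3 events for a correlation, got {n}")
    speeds = np.array([e.speed for e in events])
    lengths = np.array([e.L_ini for e in events])
    if np.ptp(speeds) == 0 or np.ptp(lengths) == 0:
        raise ValueError("correlation undefined: zero variance in speed or length")
    if method == "pearson":
        r, p = stats.pearsonr(speeds, lengths)
    elif method == "spearman":
        r, p = stats.spearmanr(speeds, lengths)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p), n


def mean_retraction_speed(
    events_by_replicate: Mapping[str, Sequence[RetractionEvent]],
) -> tuple[float, dict[str, float], float | None]:
    """Replicate-aware mean speed (SuperPlot convention).

    Per-replicate means are computed over events first; the grand mean and
    the SEM are then taken across those replicate means (the replicate, not
    the event, is the statistical unit).  SEM is ``None`` with a single
    replicate — it needs at least two.
    """
    if not events_by_replicate:
        raise ValueError("no events")
    rep_means: dict[str, float] = {}
    for rep, evs in events_by_replicate.items():
        if len(evs) == 0:
            raise ValueError(f"replicate {rep!r} has no events")
        rep_means[rep] = float(np.mean([e.speed for e in evs]))
    vals = np.array(list(rep_means.values()))
    grand = float(vals.mean())
    sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) >= 2 else None
    return grand, rep_means, sem


def events_to_dataframe(events: Iterable[RetractionEvent]) -> pd.DataFrame:
    rows = [(e.cell_id, e.pilus_id, e.t_ini, e.t_final, e.L_ini, e.L_final, e.speed)
            for e in events]
    return pd.DataFrame(rows, columns=EVENTS_COLUMNS)
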