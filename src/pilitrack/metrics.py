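"""Per-track motility statistics.

For each track this module computes:

* net displacement — Euclidean distance between first and last positions
  (the "track displacement" of standard tracking software);
* path length — summed step lengths over observed points;
* persistence (confinement) ratio — net displacement / path length, 1 for a
  perfectly straight monotone track, near 0 for confined wandering;
* the all-pairs MSD curve — for every lag τ that is a multiple of the frame
  interval, the mean of |r_j − r_i|² over *all* point pairs separated by τ;
* α — the ordinary-least-squares slope of log MSD vs log lag, the
  anomalous-diffusion exponent (≈1 random walk, 2 ballistic, ≪1 tethered);
* a motility class (non_motile / motile / roller) and a diffusion class
  (subdiffusive / diffusive / superdiffusive / undefined).

MSD is translation-invariant, so aligning trajectories to a common origin
before analysis (a common plotting convention) does not change α.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .io import Cohort, Track

__all__ = [
    "MSDCurve",
    "TrackMetrics",
    "net_displacement",
    "path_length",
    "persistence_ratio",
    "msd_all_pairs",
    "fit_alpha",
    "classify",
    "compute_track_metrics",
    "compute_cohort_metrics",
]

METRICS_COLUMNS = [
    "track_id", "group", "replicate_id", "net_displacement_um",
    "path_length_um", "persistence_ratio", "alpha",
    "motility_class", "diffusion_class",
]


@dataclass
class MSDCurve:
    """All-pairs mean squared displacement: lag (s) -> MSD (µm²), with pair counts."""

    lags: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.msd < 0):
            raise ValueError("msd must be >= 0")
        if np.any(self.n_pairs < 1):
            raise ValueError("each reported lag needs >= 1 pair")


@dataclass
class TrackMetrics:
    track_id: str
    group: str
    replicate_id: str
    net_displacement: float
    path_length: float
    persistence_ratio: float
    alpha: float | None
    motility_class: str
    diffusion_class: str


def _require_points(track: Track, n: int = 2) -> None:
    if len(track) < n:
        raise ValueError(
            f"track {track.track_id!r}: needs >= {n} points, has {len(track)}"
        )


def net_displacement(track: Track) -> float:
    """Euclidean distance between the first and last positions (µm)."""
    _require_points(track)
    r = track.positions
    return float(np.linalg.norm(r[-1] - r[0]))


def path_length(track: Track) -> float:
    """Sum of Euclidean distances between consecutive observed points (µm)."""
    _require_points(track)
    r = track.positions
    return float(np.sum(np.linalg.norm(np.diff(r, axis=0), axis=1)))


def persistence_ratio(track: Track) -> float:
    """net_displacement / path_length; 0 by convention when path_length is 0."""
    _require_points(track)
    p = path_length(track)
    if p == 0.0:
        return 0.0
    return net_displacement(track) / p


def msd_all_pairs(track: Track) -> MSDCurve:
    """All-pairs MSD over every lag that is a multiple of the frame interval.

    Pairs are formed only between observed points; in gapped tracks, lags
    with no pair are omitted from the curve.
    """
    _require_points(track)
    idx = track.frame_indices()
    r = track.positions
    n_frames = int(idx[-1]) + 1
    # dense frame grid: present-mask + positions; pairs at lag k are the
    # frames where both mask[i] and mask[i+k] hold
    present = np.zeros(n_frames, dtype=bool)
    pos = np.zeros((n_frames, 2))
    present[idx] = True
    pos[idx] = r
    lags, msds, counts = [], [], []
    for k in range(1, n_frames):
        both = present[:-k] & present[k:]
        m = int(both.sum())
        if m == 0:
            continue
        d = pos[k:][both] - pos[:-k][both]
        lags.append(k * track.frame_interval)
        msds.append(float(np.mean(np.sum(d * d, axis=1))))
        counts.append(m)
    return MSDCurve(np.array(lags), np.array(msds), np.array(counts))


def fit_alpha(
    msd: MSDCurve,
    max_lag_fraction: float = 0.25,
    duration: float | None = None,
) -> float | None:
    """OLS slope of log MSD vs log lag over lags <= max_lag_fraction * duration.

    Lags with MSD = 0 are dropped (log undefined).  Returns ``None`` when
    fewer than two usable lags remain — the slope is then undefined, which
    happens for e.g. perfectly stationary tracks.
    """
    if len(msd.lags) == 0:
        raise ValueError("empty MSD curve")
    if duration is None:
        duration = float(msd.lags[-1])
    keep = (msd.lags <= max_lag_fraction * duration + 1e-12) & (msd.msd > 0)
    if keep.sum() < 2:
        return None
    x = np.log(msd.lags[keep])
    y = np.log(msd.msd[keep])
    slope = np.polyfit(x, y, 1)[0]
    return float(slope)


def classify(
    net_disp: float,
    pers_ratio: float,
    alpha: float | None,
    config: AnalysisConfig,
) -> tuple[str, str]:
    """Assign (motility_class, diffusion_class) from the scalar metrics.

    non_motile: net displacement below the configured threshold (default 2 µm
    over the 5-min window).  roller: long, straight track — a detached cell
    carried by convection flow.  Otherwise motile (twitching).
    """
    if net_disp < config.non_motile_threshold:
        motility = "non_motile"
    elif (net_disp >= config.roller_displacement_min
          and pers_ratio >= config.roller_persistence_min):
        motility = "roller"
    else:
        motility = "motile"
    if alpha is None:
        diffusion = "undefined"
    elif alpha < config.alpha_subdiffusive_max:
        diffusion = "subdiffusive"
    elif alpha > config.alpha_superdiffusive_min:
        diffusion = "superdiffusive"
    else:
        diffusion = "diffusive"
    return motility, diffusion


def compute_track_metrics(track: Track, config: AnalysisConfig | None = None) -> TrackMetrics:
    config = config or AnalysisConfig()
    nd = net_displacement(track)
    pl = path_length(track)
    pr = 0.0 if pl == 0.0 else nd / pl
    curve = msd_all_pairs(track)
    alpha = fit_alpha(curve, config.msd_max_lag_fraction, duration=track.duration)
    motility, diffusion = classify(nd, pr, alpha, config)
    return TrackMetrics(
        track_id=track.track_id, group=track.group, replicate_id=track.replicate_id,
        net_displacement=nd, path_length=pl, persistence_ratio=pr, alpha=alpha,
        motility_class=motility, diffusion_class=diffusion,
    )


def compute_cohort_metrics(cohort: Cohort, config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Per-track metrics table for a whole cohort (one row per track)."""
    rows = []
    for tr in cohort.tracks:
        m = compute_track_metrics(tr, config)
        rows.append((m.track_id, m.group, m.replicate_id, m.net_displacement,
                     m.path_length, m.persistence_ratio,
                     np.nan if m.alpha is None else m.alpha,
                     m.motility_class, m.diffusion_class))
    return pd.DataFrame(rows, columns=METRICS_COLUMNS)
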