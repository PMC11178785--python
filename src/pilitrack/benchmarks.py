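"""Headline cohort statistics computed end-to-end from the package itself.

These functions run the full pipeline — simulate, measure, summarise — and
return the quantities the package is validated against: the mean MSD slope
of pure random walks, retraction-speed recovery from noisy traces, and the
frozen-preset cohort statistics (mean displacement, persistence ratio,
non-motile percentage).

Cohort-level statistics at the published sample sizes (N ≈ 200) carry
appreciable sampling noise, so ``cohort_statistics`` can average a handful
of independently-seeded cohorts simulated under identical conditions; the
per-cohort conditions (preset, N, replicate count) are never changed.
"""

from __future__ import annotations

import numpy as np

from .config import AnalysisConfig
from .metrics import compute_cohort_metrics, fit_alpha, msd_all_pairs
from .retraction import detect_retractions, principal_event
from .simulate import (
    builtin_presets,
    simulate_cohort,
    simulate_random_walk_cohort,
    simulate_retraction_trace,
)

__all__ = [
    "random_walk_mean_alpha",
    "retraction_speed_recovery",
    "cohort_statistics",
]


def random_walk_mean_alpha(
    n_tracks: int = 200,
    n_frames: int = 300,
    step_sd: float = 0.3,
    seed: int = 0,
    max_lag_fraction: float = 0.25,
) -> float:
    """Mean per-track log-log MSD slope over unbiased 2-D random walks."""
    cohort = simulate_random_walk_cohort(n_tracks, n_frames, step_sd, seed=seed)
    alphas = []
    for tr in cohort.tracks:
        a = fit_alpha(msd_all_pairs(tr), max_lag_fraction, tr.duration)
        if a is not None:
            alphas.append(a)
    return float(np.mean(alphas))


def retraction_speed_recovery(
    n_traces: int = 19,
    true_speed: float = 0.3,
    noise_sd: float = 0.05,
    frame_interval: float = 0.5,
    seed: int = 0,
) -> float:
    """Mean endpoint-estimated speed over noisy single-pilus traces
    generated at a known true speed (initial lengths uniform in 2-8 µm)."""
    est = []
    for i in range(n_traces):
        rng = np.random.default_rng([seed, i + 1])
        L0 = rng.uniform(2.0, 8.0)
        trace, _ = simulate_retraction_trace(true_speed, L0, noise_sd=noise_sd,
                                             frame_interval=frame_interval, seed=rng)
        ev = principal_event(detect_retractions(trace))
        if ev is not None:
            est.append(ev.speed)
    return float(np.mean(est))


def cohort_statistics(
    preset_name: str,
    n_tracks: int,
    n_replicates: int = 3,
    seed: int = 0,
    n_repeats: int = 1,
    config: AnalysisConfig | None = None,
) -> dict[str, float]:
    """Frozen-preset cohort statistics, averaged over ``n_repeats``
    independently seeded cohorts of identical size.

    Returns mean net displacement and mean persistence ratio (each the
    grand mean of replicate means, SuperPlot convention) and the percentage
    of tracks classified non-motile.
    """
    config = config or AnalysisConfig()
    preset = builtin_presets()[preset_name]
    disp, pers, pct_nm = [], [], []
    for r in range(n_repeats):
        cohort, _ = simulate_cohort(preset, n_tracks, n_replicates,
                                    seed=int(seed + 1000 * r))
        m = compute_cohort_metrics(cohort, config)
        disp.append(m.groupby("replicate_id")["net_displacement_um"].mean().mean())
        pers.append(m.groupby("replicate_id")["persistence_ratio"].mean().mean())
        pct_nm.append((m["motility_class"] == "non_motile").mean() * 100.0)
    return {
        "mean_net_displacement_um": float(np.mean(disp)),
        "mean_persistence_ratio": float(np.mean(pers)),
        "percent_non_motile": float(np.mean(pct_nm)),
        "n_tracks": int(n_tracks),
    }
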