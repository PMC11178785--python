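"""Mechanistic simulator of pilus-retraction-driven twitching motility.

Cells are points moving in a plane.  Three behavioural modes are modelled,
matching what live-cell imaging of surface-adhered Sulfolobus shows:

``twitcher``
    Adhesion pili nucleate as a Poisson process, each with a uniform random
    direction and a length drawn from a truncated normal (capped at the
    longest observed fibres, 14 µm).  The tip anchors to the surface and the
    fibre retracts at a per-pilus speed drawn from a truncated normal
    supported on the measured 0.3–2 µm/s range.  While a single pilus is
    attached the cell advances toward its anchor at the retraction speed;
    with several attached it advances toward the equal-weight centroid of
    the anchors (a tug-of-war that lands the cell "in the middle" of the
    remaining adhered pili).  When a retraction completes, the cell takes a
    single backward recoil step with configurable probability — the slip
    seen when surface attachment is lost.  The result is a saltatory,
    low-persistence random walk.

``tethered``
    Isotropic Gaussian wobble about a fixed anchor point — a cell held in
    place (non-motile).

``roller``
    After a random dwell, straight constant-velocity motion: a detached
    cell carried by convection flow, producing a long high-persistence
    track.  With a near-zero speed this mode also serves as a slow residual
    creep for loosely-attached cells.

Every sampled position receives isotropic Gaussian localisation noise.
Reproducibility: one root seed; track *i* of a cohort uses the dedicated
generator ``np.random.default_rng([seed, i + 1])`` (mode assignment uses
stream 0), so output is bit-identical regardless of iteration order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import yaml

from .io import Cohort, PilusTrace, Track, TrackPoint, MAX_PILUS_LENGTH_UM

__all__ = [
    "PhenotypePreset",
    "TrackTruth",
    "RetractionTruth",
    "simulate_track",
    "simulate_cohort",
    "simulate_retraction_trace",
    "simulate_random_walk_track",
    "simulate_random_walk_cohort",
    "builtin_presets",
    "MODES",
]

MODES = ("twitcher", "tethered", "roller")


@dataclass
class PhenotypePreset:
    """Simulator parameter bundle reproducing one strain-like behaviour.

    The numeric values of the packaged presets (see :func:`builtin_presets`)
    were fixed once by a coarse grid search against the published cohort
    statistics and are frozen; they are not meant to be tuned per run.
    """

    name: str
    #: probabilities over (twitcher, tethered, roller); must sum to 1
    mode_fractions: dict[str, float]
    #: pilus nucleation rate (events/s) in twitcher mode
    pilus_nucleation_rate: float = 0.0263
    #: truncated-normal pilus length: (mean µm, sd µm, max µm)
    pilus_length_params: tuple[float, float, float] = (2.5, 0.7, MAX_PILUS_LENGTH_UM)
    #: truncated-normal retraction speed: (mean, sd, lo, hi) µm/s
    retraction_speed_params: tuple[float, float, float, float] = (0.3, 0.3, 0.3, 2.0)
    #: maximum simultaneously attached pili
    multi_pilus_max: int = 3
    #: backward slip on completion of a retraction
    recoil_step: float = 0.3
    recoil_prob: float = 0.3
    #: sd of the wobble about the anchor in tethered mode (µm)
    tether_jitter_sd: float = 0.05
    #: roller velocity (mean, sd) µm/s and mean exponential dwell before detachment (s)
    roller_speed: float = 0.12
    roller_speed_sd: float = 0.03
    roller_dwell_mean_s: float = 60.0
    #: isotropic localisation noise added to every sampled position (µm)
    localization_noise_sd: float = 0.058
    #: movie length (s) and sampling interval (s)
    duration: float = 300.0
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        missing = [m for m in MODES if m not in self.mode_fractions]
        if missing:
            self.mode_fractions = {m: self.mode_fractions.get(m, 0.0) for m in MODES}
        fr = [self.mode_fractions[m] for m in MODES]
        if any(f < 0 or f > 1 for f in fr):
            raise ValueError("mode fractions must be in [0, 1]")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError(f"mode fractions must sum to 1, got {sum(fr)}")
        mean, sd, mx = self.pilus_length_params
        if mean <= 0 or sd <= 0 or mx <= 0:
            raise ValueError("pilus length parameters must be positive")
        vm, vs, lo, hi = self.retraction_speed_params
        if not (0 < lo < hi):
            raise ValueError("retraction speed support must satisfy 0 < lo < hi")
        if not (0.3 - 1e-9 <= lo and hi <= 2.0 + 1e-9):
            raise ValueError("retraction speed support must lie within [0.3, 2] µm/s")
        for nm in ("pilus_nucleation_rate", "duration", "frame_interval"):
            if getattr(self, nm) <= 0:
                raise ValueError(f"{nm} must be positive")
        for nm in ("recoil_step", "tether_jitter_sd", "roller_speed",
                   "roller_speed_sd", "roller_dwell_mean_s", "localization_noise_sd"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be >= 0")
        if not (0.0 <= self.recoil_prob <= 1.0):
            raise ValueError("recoil_prob must be a probability")
        if self.multi_pilus_max < 1:
            raise ValueError("multi_pilus_max must be >= 1")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.frame_interval))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pilus_length_params"] = list(self.pilus_length_params)
        d["retraction_speed_params"] = list(self.retraction_speed_params)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhenotypePreset":
        d = dict(d)
        for key in ("pilus_length_params", "retraction_speed_params"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PhenotypePreset":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class TrackTruth:
    """Ground truth for one simulated track (for parameter-recovery tests)."""

    mode: str
    true_positions: np.ndarray  # (n_frames, 2), noise-free
    event_speeds: list[float] = field(default_factory=list)
    anchor: tuple[float, float] | None = None


@dataclass
class RetractionTruth:
    true_speed: float
    L0: float


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    """Draw by rejection; falls back to uniform on pathological parameters."""
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo < v <= hi:
            return float(v)
    return float(rng.uniform(lo, hi))


def _unit(theta: float) -> np.ndarray:
    return np.array([math.cos(theta), math.sin(theta)])


def _simulate_twitcher(
    preset: PhenotypePreset,
    rng: np.random.Generator,
    forced_pili: Sequence[tuple[float, float, float, float]] | None = None,
    n_substeps: int = 5,
) -> tuple[np.ndarray, list[float]]:
    """Integrate the pilus tug-of-war; returns noise-free frame positions and
    the true retraction speed of every nucleated pilus.

    ``forced_pili`` — sequence of (t_nucleate, angle_rad, length_um, speed)
    — replaces Poisson nucleation entirely; used for hand-checkable runs.
    """
    dt = preset.frame_interval / n_substeps
    n_frames = preset.n_frames
    lmean, lsd, lmax = preset.pilus_length_params
    vmean, vsd, vlo, vhi = preset.retraction_speed_params
    pos = np.zeros(2)
    active: list[dict] = []
    speeds: list[float] = []
    forced = sorted(forced_pili, key=lambda p: p[0]) if forced_pili is not None else None
    fi = 0
    out = np.zeros((n_frames, 2))
    out[0] = pos
    t = 0.0
    for frame in range(1, n_frames):
        for _ in range(n_substeps):
            # nucleation
            if forced is not None:
                while fi < len(forced) and forced[fi][0] <= t + 1e-12:
                    t0, ang, length, speed = forced[fi]
                    fi += 1
                    if len(active) < preset.multi_pilus_max:
                        anchor = pos + length * _unit(ang)
                        active.append({"anchor": anchor, "speed": speed,
                                       "t_detach": t + length / speed,
                                       "last_dir": _unit(ang)})
                        speeds.append(speed)
            elif len(active) < preset.multi_pilus_max:
                if rng.random() < preset.pilus_nucleation_rate * dt:
                    ang = rng.uniform(0.0, 2.0 * math.pi)
                    length = _truncated_normal(rng, lmean, lsd, 0.0, lmax)
                    speed = _truncated_normal(rng, vmean, vsd, vlo, vhi)
                    anchor = pos + length * _unit(ang)
                    active.append({"anchor": anchor, "speed": speed,
                                   "t_detach": t + length / speed,
                                   "last_dir": _unit(ang)})
                    speeds.append(speed)
            # motion toward the anchor centroid
            if active:
                target = np.mean([p["anchor"] for p in active], axis=0)
                delta = target - pos
                dist = float(np.linalg.norm(delta))
                v = float(np.mean([p["speed"] for p in active]))
                if dist > 1e-12:
                    step = min(v * dt, dist)
                    direction = delta / dist
                    pos = pos + step * direction
                    for p in active:
                        d = p["anchor"] - pos
                        nd = float(np.linalg.norm(d))
                        if nd > 1e-12:
                            p["last_dir"] = d / nd
            t += dt
            # completed retractions detach; possible backward slip
            still = []
            for p in active:
                if t + 1e-12 >= p["t_detach"]:
                    if preset.recoil_prob > 0 and rng.random() < preset.recoil_prob:
                        pos = pos - preset.recoil_step * p["last_dir"]
                else:
                    still.append(p)
            active = still
        out[frame] = pos
    return out, speeds


def simulate_track(
    preset: PhenotypePreset,
    mode: str,
    seed: "int | np.random.Generator",
    forced_pili: Sequence[tuple[float, float, float, float]] | None = None,
) -> tuple[Track, TrackTruth]:
    """Simulate a single track in the given behavioural mode.

    ``seed`` may be an integer or an existing Generator.  ``forced_pili``
    (twitcher mode only) injects a deterministic pilus schedule in place of
    Poisson nucleation — see :func:`_simulate_twitcher`.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_frames = preset.n_frames
    times = np.arange(n_frames) * preset.frame_interval
    speeds: list[float] = []
    anchor = None
    if mode == "twitcher":
        true_pos, speeds = _simulate_twitcher(preset, rng, forced_pili=forced_pili)
    elif mode == "tethered":
        anchor = (0.0, 0.0)
        if preset.tether_jitter_sd > 0:
            true_pos = rng.normal(0.0, preset.tether_jitter_sd, (n_frames, 2))
        else:
            true_pos = np.zeros((n_frames, 2))
    elif mode == "roller":
        dwell = (rng.exponential(preset.roller_dwell_mean_s)
                 if preset.roller_dwell_mean_s > 0 else 0.0)
        speed = preset.roller_speed
        if preset.roller_speed_sd > 0:
            speed = max(rng.normal(preset.roller_speed, preset.roller_speed_sd), 1e-6)
        direction = _unit(rng.uniform(0.0, 2.0 * math.pi))
        travel = np.clip(times - dwell, 0.0, None) * speed
        true_pos = travel[:, None] * direction[None, :]
    else:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    obs = true_pos.copy()
    if preset.localization_noise_sd > 0:
        obs = obs + rng.normal(0.0, preset.localization_noise_sd, obs.shape)
    points = [TrackPoint(t=float(t), x=float(x), y=float(y))
              for t, (x, y) in zip(times, obs)]
    track = Track(track_id="sim-0", replicate_id="rep1", group=preset.name,
                  points=points, frame_interval=preset.frame_interval)
    return track, TrackTruth(mode=mode, true_positions=true_pos,
                             event_speeds=speeds, anchor=anchor)


def simulate_cohort(
    preset: PhenotypePreset,
    n_tracks: int,
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[Cohort, dict[str, TrackTruth]]:
    """Simulate a cohort: modes drawn i.i.d. from the preset's mode
    fractions, tracks assigned round-robin to replicates.

    Identical (preset, n_tracks, n_replicates, seed) yields bit-identical
    output: each track has its own seeded stream keyed by (seed, index).
    """
    if n_tracks < 1:
        raise ValueError("n_tracks must be >= 1")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    mode_rng = np.random.default_rng([seed, 0])
    probs = [preset.mode_fractions[m] for m in MODES]
    modes = mode_rng.choice(len(MODES), size=n_tracks, p=probs)
    tracks: list[Track] = []
    truths: dict[str, TrackTruth] = {}
    for i in range(n_tracks):
        rng = np.random.default_rng([seed, i + 1])
        track, truth = simulate_track(preset, MODES[modes[i]], rng)
        track.track_id = f"{preset.name}-{i:04d}"
        track.replicate_id = f"rep{(i % n_replicates) + 1}"
        tracks.append(track)
        truths[track.track_id] = truth
    return Cohort(tracks=tracks), truths


def simulate_retraction_trace(
    true_speed: float,
    L0: float,
    noise_sd: float = 0.05,
    frame_interval: float = 0.5,
    seed: "int | np.random.Generator" = 0,
    cell_id: str = "cell-0",
    pilus_id: str = "pilus-0",
    max_length: float = MAX_PILUS_LENGTH_UM,
) -> tuple[PilusTrace, RetractionTruth]:
    """A single-pilus retraction trace: length falls linearly from L0 to 0
    at ``true_speed``, sampled every ``frame_interval`` (default 0.5 s, the
    fluorescence imaging rate), with additive Gaussian noise clipped at 0."""
    if true_speed <= 0:
        raise ValueError("true_speed must be positive")
    if not (0 < L0 <= max_length):
        raise ValueError(f"L0 must be in (0, {max_length}]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    T = L0 / true_speed
    # sample only while the fibre exists: the last frame is the final on-grid
    # time <= T, so the endpoint estimate is exact on noiseless traces even
    # when T is not a multiple of the frame interval
    n = int(math.floor(T / frame_interval + 1e-9)) + 1
    times = np.arange(n) * frame_interval
    lengths = np.clip(L0 - true_speed * times, 0.0, None)
    if noise_sd > 0:
        lengths = np.clip(lengths + rng.normal(0.0, noise_sd, n), 0.0, max_length)
    samples = [(float(t), float(ln)) for t, ln in zip(times, lengths)]
    trace = PilusTrace(cell_id, pilus_id, samples, max_length=max_length)
    return trace, RetractionTruth(true_speed=true_speed, L0=L0)


def simulate_random_walk_track(
    n_frames: int = 300,
    step_sd: float = 0.3,
    frame_interval: float = 1.0,
    seed: "int | np.random.Generator" = 0,
    track_id: str = "rw-0",
    replicate_id: str = "rep1",
    group: str = "random_walk",
) -> Track:
    """An unbiased isotropic Gaussian-step 2-D random walk (diffusive, α≈1)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    steps = rng.normal(0.0, step_sd, (n_frames - 1, 2))
    pos = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
    times = np.arange(n_frames) * frame_interval
    points = [TrackPoint(float(t), float(x), float(y))
              for t, (x, y) in zip(times, pos)]
    return Track(track_id=track_id, replicate_id=replicate_id, group=group,
                 points=points, frame_interval=frame_interval)


def simulate_random_walk_cohort(
    n_tracks: int = 200,
    n_frames: int = 300,
    step_sd: float = 0.3,
    frame_interval: float = 1.0,
    seed: int = 0,
) -> Cohort:
    tracks = []
    for i in range(n_tracks):
        rng = np.random.default_rng([seed, i + 1])
        tracks.append(
            simulate_random_walk_track(n_frames, step_sd, frame_interval, rng,
                                       track_id=f"rw-{i:04d}",
                                       replicate_id=f"rep{(i % 3) + 1}")
        )
    return Cohort(tracks=tracks)


def builtin_presets() -> dict[str, PhenotypePreset]:
    """Frozen default presets for the strain-like behaviours.

    Mode fractions and kinetic parameters were calibrated once (coarse grid
    search on small cohorts against the published summary statistics) and
    are fixed here verbatim; `WT` reproduces the wild-type twitching
    statistics, `daapF` the adhesion-pilus-less tether-dominated phenotype,
    `darlJ` the archaellum-less (almost fully motile) phenotype and `daapB`
    the loosely-attached phenotype with a detaching "roller" subpopulation.
    """
    presets = {}
    presets["WT"] = PhenotypePreset(
        name="WT",
        mode_fractions={"twitcher": 0.96, "tethered": 0.04, "roller": 0.0},
    )
    presets["darlJ"] = PhenotypePreset(
        name="darlJ",
        mode_fractions={"twitcher": 1.0, "tethered": 0.0, "roller": 0.0},
    )
    presets["dupsE"] = PhenotypePreset(
        name="dupsE",
        mode_fractions={"twitcher": 0.91, "tethered": 0.09, "roller": 0.0},
    )
    presets["dupsE_darlJ"] = PhenotypePreset(
        name="dupsE_darlJ",
        mode_fractions={"twitcher": 0.945, "tethered": 0.055, "roller": 0.0},
    )
    # Adhesion-pilus assembly mutant: no twitching.  A tight wobbling
    # population plus a slow residual creep (near-stationary drift of
    # loosely held cells) reproduces the published mean displacement and
    # sub-2 µm fraction, which no single wobble amplitude can.
    presets["daapF"] = PhenotypePreset(
        name="daapF",
        mode_fractions={"twitcher": 0.0, "tethered": 0.40, "roller": 0.60},
        roller_speed=0.008,
        roller_speed_sd=0.001,
        roller_dwell_mean_s=0.0,
    )
    # Major-pilin mutant: mostly tethered, but loosely attached cells
    # detach and roll away on convection flow, generating long tracks.
    presets["daapB"] = PhenotypePreset(
        name="daapB",
        mode_fractions={"twitcher": 0.0, "tethered": 0.85, "roller": 0.15},
        roller_speed=0.12,
        roller_speed_sd=0.03,
        roller_dwell_mean_s=60.0,
    )
    return presets
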