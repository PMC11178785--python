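"""End-to-end validation stage: render synthetic movies, detect, re-link.

This closes the loop simulate -> render -> detect -> link -> metrics so the
track statistics can be stress-tested against realistic tracking noise.
Cells are drawn as isotropic Gaussian blobs (sd = cell_radius / 2; radius
default 0.8 µm, half the mean cell diameter) over additive Gaussian
background noise; detection is smooth/threshold/connected-components with
intensity-weighted centroids; linking is greedy nearest-neighbour with gap
bridging.  Appearance is deliberately generic bright-blob imagery — the
point is tracking noise, not microscope physics.

Pixel convention: position (0, 0) µm maps to the *centre* of pixel (0, 0),
so µm = pixel_index * pixel_size on each axis (row -> y, column -> x).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import gaussian as _skimage_gaussian
from skimage.measure import label as _sk_label, regionprops

from .io import Cohort, Track, TrackPoint

__all__ = [
    "SyntheticMovie",
    "render_movie",
    "detect_cells",
    "detect_movie",
    "link_tracks",
    "arrange_on_grid",
    "match_fraction",
]

DEFAULT_CELL_RADIUS_UM = 0.8


@dataclass
class SyntheticMovie:
    frames: np.ndarray  # (n_frames, H, W) float32
    pixel_size: float  # µm / pixel
    frame_interval: float  # s
    #: frame index -> list of (track_id, x_um, y_um) true centroids
    ground_truth: dict[int, list[tuple[str, float, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, H, W) stack")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


def arrange_on_grid(cohort: Cohort, spacing_um: float = 25.0, margin_um: float = 8.0) -> Cohort:
    """Translate each track's start onto a square grid so a whole simulated
    cohort (every track starts at the origin) fits one field of view without
    overlap.  Track metrics are translation-invariant, so this changes
    nothing downstream."""
    n = len(cohort.tracks)
    side = int(math.ceil(math.sqrt(n)))
    new_tracks = []
    for i, tr in enumerate(cohort.tracks):
        ox = margin_um + (i % side) * spacing_um
        oy = margin_um + (i // side) * spacing_um
        pts = [TrackPoint(p.t, p.x + ox, p.y + oy) for p in tr.points]
        new_tracks.append(Track(tr.track_id, tr.replicate_id, tr.group, pts,
                                tr.frame_interval))
    return Cohort(tracks=new_tracks)


def render_movie(
    cohort: Cohort,
    pixel_size: float = 0.2,
    cell_radius: float = DEFAULT_CELL_RADIUS_UM,
    snr: float = 10.0,
    seed: int = 0,
    shape: tuple[int, int] | None = None,
) -> SyntheticMovie:
    """Render a cohort as a synthetic movie.

    Each cell is an isotropic Gaussian blob of unit peak amplitude and
    sd = cell_radius / 2 at its current position; background noise is
    Gaussian with sd = 1 / snr.  All tracks must share the frame interval
    and fit the field (an explicit error lists any offender).
    """
    if len(cohort.tracks) > 0:
        intervals = {t.frame_interval for t in cohort.tracks}
        if len(intervals) != 1:
            raise ValueError(f"tracks have mixed frame intervals: {sorted(intervals)}")
        frame_interval = intervals.pop()
        n_frames = max(int(t.frame_indices()[-1]) + 1 for t in cohort.tracks)
    else:
        frame_interval = 1.0
        n_frames = 1
    if shape is None:
        if cohort.tracks:
            xs = np.concatenate([t.positions[:, 0] for t in cohort.tracks])
            ys = np.concatenate([t.positions[:, 1] for t in cohort.tracks])
            pad = 4.0 * cell_radius
            W = int(math.ceil((xs.max() + pad) / pixel_size)) + 1
            H = int(math.ceil((ys.max() + pad) / pixel_size)) + 1
        else:
            H = W = 64
        shape = (H, W)
    H, W = shape
    offenders = []
    for t in cohort.tracks:
        r = t.positions
        if (r[:, 0].min() < 0 or r[:, 1].min() < 0
                or r[:, 0].max() > (W - 1) * pixel_size
                or r[:, 1].max() > (H - 1) * pixel_size):
            offenders.append(t.track_id)
    if offenders:
        raise ValueError(f"track(s) outside field of view: {offenders}")

    rng = np.random.default_rng(seed)
    sigma_px = (cell_radius / 2.0) / pixel_size
    half = max(int(math.ceil(4 * sigma_px)), 2)
    frames = np.zeros((n_frames, H, W), dtype=np.float32)
    truth: dict[int, list[tuple[str, float, float]]] = {k: [] for k in range(n_frames)}
    for tr in cohort.tracks:
        idx = tr.frame_indices()
        for k, (x, y) in zip(idx, tr.positions):
            cx, cy = x / pixel_size, y / pixel_size
            x0, x1 = max(int(cx) - half, 0), min(int(cx) + half + 1, W)
            y0, y1 = max(int(cy) - half, 0), min(int(cy) + half + 1, H)
            xs = np.arange(x0, x1)
            ys = np.arange(y0, y1)
            gx = np.exp(-0.5 * ((xs - cx) / sigma_px) ** 2)
            gy = np.exp(-0.5 * ((ys - cy) / sigma_px) ** 2)
            frames[k, y0:y1, x0:x1] += np.outer(gy, gx).astype(np.float32)
            truth[int(k)].append((tr.track_id, float(x), float(y)))
    if np.isfinite(snr):
        frames += rng.normal(0.0, 1.0 / snr, frames.shape).astype(np.float32)
    return SyntheticMovie(frames=frames, pixel_size=pixel_size,
                          frame_interval=frame_interval, ground_truth=truth)


def detect_cells(
    frame: np.ndarray,
    pixel_size: float,
    threshold_sd: float = 4.0,
    min_area_px: int = 4,
    smoothing_sigma_px: float = 1.0,
) -> np.ndarray:
    """Detect bright blobs in one frame; returns (n, 2) centroids in µm (x, y).

    Gaussian smoothing, global threshold at mean + threshold_sd * sd of the
    smoothed frame, connected components of at least ``min_area_px`` pixels,
    intensity-weighted centroid per component.  Touching blobs may merge
    into one component — a documented limitation of global thresholding.
    """
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite values")
    sm = _skimage_gaussian(frame.astype(float), sigma=smoothing_sigma_px,
                           preserve_range=True)
    thr = sm.mean() + threshold_sd * sm.std()
    mask = sm > thr
    lab = _sk_label(mask)
    out = []
    for rp in regionprops(lab, intensity_image=sm):
        if rp.area < min_area_px:
            continue
        cy, cx = rp.centroid_weighted
        out.append((cx * pixel_size, cy * pixel_size))
    return np.array(out).reshape(-1, 2)


def detect_movie(movie: SyntheticMovie, **kwargs) -> list[np.ndarray]:
    """Per-frame detections for a whole movie (list of (n_k, 2) µm arrays)."""
    return [detect_cells(f, movie.pixel_size, **kwargs) for f in movie.frames]


def link_tracks(
    detections: list[np.ndarray],
    frame_interval: float = 1.0,
    max_disp: float = 2.0,
    max_gap: int = 2,
    group: str = "relinked",
    replicate_id: str = "rep1",
    min_length: int = 2,
) -> Cohort:
    """Greedy nearest-neighbour frame-to-frame linking with gap bridging.

    Candidate links are accepted in ascending distance order up to
    ``max_disp`` µm per elapsed frame (so a track lost for g frames may jump
    g * max_disp); a track unmatched for more than ``max_gap`` frames is
    terminated.  Each detection joins at most one track.  ``max_disp``
    defaults to 2 µm/frame, comfortably above the largest twitch step.
    """
    active: list[dict] = []
    done: list[dict] = []
    for k, dets in enumerate(detections):
        dets = np.asarray(dets, dtype=float).reshape(-1, 2)
        still_active = [tr for tr in active if k - tr["last_frame"] <= max_gap]
        done.extend(tr for tr in active if k - tr["last_frame"] > max_gap)
        active = still_active
        used: set[int] = set()
        if len(active) and len(dets):
            cand = []
            for ti, tr in enumerate(active):
                gap = k - tr["last_frame"]
                d = np.linalg.norm(dets - tr["pos"], axis=1)
                for di in range(len(dets)):
                    if d[di] <= max_disp * gap:
                        cand.append((d[di], ti, di))
            cand.sort(key=lambda c: c[0])
            matched_tracks: set[int] = set()
            for dist, ti, di in cand:
                if ti in matched_tracks or di in used:
                    continue
                tr = active[ti]
                tr["frames"].append(k)
                tr["points"].append(dets[di])
                tr["pos"] = dets[di]
                tr["last_frame"] = k
                matched_tracks.add(ti)
                used.add(di)
        for di in range(len(dets)):
            if di not in used:
                active.append({"frames": [k], "points": [dets[di]],
                               "pos": dets[di], "last_frame": k})
    done.extend(active)
    tracks = []
    for i, tr in enumerate(sorted(done, key=lambda t: (t["frames"][0], t["points"][0][0]))):
        if len(tr["frames"]) < min_length:
            continue
        pts = [TrackPoint(t=f * frame_interval, x=float(p[0]), y=float(p[1]))
               for f, p in zip(tr["frames"], tr["points"])]
        tracks.append(Track(track_id=f"link-{i:04d}", replicate_id=replicate_id,
                            group=group, points=pts, frame_interval=frame_interval))
    return Cohort(tracks=tracks)


def match_fraction(
    recovered: Cohort,
    truth: Cohort,
    tol_um: float = 1.0,
) -> dict[str, tuple[str | None, float]]:
    """For each recovered track: the best-matching ground-truth track and the
    fraction of its frames that lie within ``tol_um`` of that truth track."""
    truth_pos = {}
    for tr in truth.tracks:
        truth_pos[tr.track_id] = dict(zip(tr.frame_indices().tolist(),
                                          map(tuple, tr.positions)))
    out = {}
    for tr in recovered.tracks:
        frames = tr.frame_indices().tolist()
        pos = tr.positions
        best, best_frac = None, 0.0
        for tid, tp in truth_pos.items():
            hits = 0
            for f, p in zip(frames, pos):
                q = tp.get(f)
                if q is not None and math.hypot(p[0] - q[0], p[1] - q[1]) <= tol_um:
                    hits += 1
            frac = hits / len(frames)
            if frac > best_frac:
                best, best_frac = tid, frac
        out[tr.track_id] = (best, best_frac)
    return out
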