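"""Domain containers and file I/O for motility tracks and pilus-length traces.

All quantities are carried in micrometres and seconds internally; importers
convert at the boundary (image-derived coordinates are converted with an
explicit, caller-supplied pixel size — never guessed).

Two plain-text table formats are defined here:

* track table  — ``track_id,replicate_id,group,t_s,x_um,y_um`` (one row per point)
* pilus trace  — ``cell_id,pilus_id,t_s,length_um``

plus a read-only importer for the spot/edge subset of TrackMate XML.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lxml import etree

__all__ = [
    "TrackPoint",
    "Track",
    "Cohort",
    "PilusTrace",
    "read_tracks",
    "write_tracks",
    "read_pilus_traces",
    "write_pilus_traces",
]

TRACK_COLUMNS = ["track_id", "replicate_id", "group", "t_s", "x_um", "y_um"]
TRACE_COLUMNS = ["cell_id", "pilus_id", "t_s", "length_um"]

#: default physical cap on pilus length (µm); adhesion fibres up to ~14 µm
#: have been observed on live Sulfolobus cells.
MAX_PILUS_LENGTH_UM = 14.0


@dataclass(frozen=True)
class TrackPoint:
    """A single localisation: time (s) and planar position (µm)."""

    t: float
    x: float
    y: float

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError(f"time must be >= 0, got {self.t}")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"position must be finite, got ({self.x}, {self.y})")


@dataclass
class Track:
    """One cell's time-ordered positions sampled at a fixed frame interval.

    Gaps (missing frames) are allowed and retained as-is: consecutive
    point spacings must be integer multiples of ``frame_interval`` but need
    not equal it.  Metrics operate on the observed points only.
    """

    track_id: str
    replicate_id: str
    group: str
    points: Sequence[TrackPoint]
    frame_interval: float

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if len(self.points) == 0:
            raise ValueError(f"track {self.track_id!r}: empty track")
        ts = [p.t for p in self.points]
        for a, b in zip(ts, ts[1:]):
            if b <= a:
                raise ValueError(
                    f"track {self.track_id!r}: time not strictly increasing "
                    f"({a} -> {b})"
                )
            k = (b - a) / self.frame_interval
            if abs(k - round(k)) > 1e-6:
                raise ValueError(
                    f"track {self.track_id!r}: spacing {b - a} is not an "
                    f"integer multiple of frame_interval={self.frame_interval}"
                )

    def __len__(self) -> int:
        return len(self.points)

    @property
    def times(self) -> np.ndarray:
        return np.array([p.t for p in self.points], dtype=float)

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of positions in µm."""
        return np.array([[p.x, p.y] for p in self.points], dtype=float)

    @property
    def duration(self) -> float:
        return self.points[-1].t - self.points[0].t

    def frame_indices(self) -> np.ndarray:
        """Integer frame index of each point relative to the first point."""
        t0 = self.points[0].t
        return np.round((self.times - t0) / self.frame_interval).astype(int)


@dataclass
class Cohort:
    """A collection of tracks with the group -> replicate structure made explicit."""

    tracks: list[Track]
    metadata: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [t.track_id for t in self.tracks]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate track_ids: {dupes}")
        if not self.metadata:
            self.metadata = {}
            for t in self.tracks:
                self.metadata.setdefault(t.group, set()).add(t.replicate_id)
        for t in self.tracks:
            if t.replicate_id not in self.metadata.get(t.group, set()):
                raise ValueError(
                    f"track {t.track_id!r}: ({t.group!r}, {t.replicate_id!r}) "
                    "missing from cohort metadata"
                )

    def __len__(self) -> int:
        return len(self.tracks)

    @property
    def groups(self) -> list[str]:
        return sorted(self.metadata)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for tr in self.tracks:
            for p in tr.points:
                rows.append((tr.track_id, tr.replicate_id, tr.group, p.t, p.x, p.y))
        return pd.DataFrame(rows, columns=TRACK_COLUMNS)


@dataclass
class PilusTrace:
    """Length of one pilus fibre over time (µm vs s)."""

    cell_id: str
    pilus_id: str
    samples: Sequence[tuple[float, float]]
    max_length: float = MAX_PILUS_LENGTH_UM

    def __post_init__(self) -> None:
        ts = [s[0] for s in self.samples]
        for a, b in zip(ts, ts[1:]):
            if b <= a:
                raise ValueError(
                    f"trace ({self.cell_id!r}, {self.pilus_id!r}): time not "
                    "strictly increasing"
                )
        for t, ln in self.samples:
            if ln < 0:
                raise ValueError("pilus length must be >= 0")
            if ln > self.max_length:
                raise ValueError(
                    f"pilus length {ln} exceeds configured maximum {self.max_length}"
                )

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def times(self) -> np.ndarray:
        return np.array([s[0] for s in self.samples], dtype=float)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([s[1] for s in self.samples], dtype=float)


# ---------------------------------------------------------------------------
# table round-trip


def _infer_frame_interval(ts: np.ndarray) -> float:
    dts = np.diff(ts)
    dts = dts[dts > 0]
    if len(dts) == 0:
        raise ValueError("cannot infer frame interval from a single point")
    return float(dts.min())


def cohort_from_dataframe(df: pd.DataFrame, frame_interval: float | None = None) -> Cohort:
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"track table missing column(s): {missing}")
    tracks = []
    for tid, sub in df.groupby("track_id", sort=False):
        sub = sub.reset_index(drop=True)
        ts = sub["t_s"].to_numpy(dtype=float)
        if np.any(np.diff(ts) <= 0):
            raise ValueError(f"track {tid!r}: time values not strictly increasing")
        dt = frame_interval if frame_interval is not None else _infer_frame_interval(ts)
        pts = [
            TrackPoint(t=float(r.t_s), x=float(r.x_um), y=float(r.y_um))
            for r in sub.itertuples()
        ]
        tracks.append(
            Track(
                track_id=str(tid),
                replicate_id=str(sub["replicate_id"].iloc[0]),
                group=str(sub["group"].iloc[0]),
                points=pts,
                frame_interval=dt,
            )
        )
    return Cohort(tracks=tracks)


def read_tracks(
    path: str | Path,
    format: str = "table",
    *,
    frame_interval: float | None = None,
    pixel_size: float | None = None,
) -> Cohort:
    """Read a cohort of tracks.

    Parameters
    ----------
    path : file path
    format : {"table", "trackmate_xml"}
    frame_interval : s, optional
        Override the frame interval (otherwise inferred as the minimum
        positive time step within each track).
    pixel_size : µm/px, optional
        Required when reading TrackMate XML whose positions are in pixels;
        positions are multiplied by this factor.  Leave ``None`` for sources
        already in µm.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "table":
        try:
            df = pd.read_csv(path, float_precision="round_trip")
        except Exception as exc:  # pragma: no cover - pandas message passthrough
            raise ValueError(f"malformed track table {path}: {exc}") from exc
        if pixel_size is not None:
            df = df.assign(x_um=df["x_um"] * pixel_size, y_um=df["y_um"] * pixel_size)
        return cohort_from_dataframe(df, frame_interval=frame_interval)
    if format == "trackmate_xml":
        return _read_trackmate(path, frame_interval=frame_interval, pixel_size=pixel_size)
    raise ValueError(f"unknown format {format!r}")


def write_tracks(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as a track table; values round-trip at full precision."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(TRACK_COLUMNS) + "\n")
        for tr in cohort.tracks:
            for p in tr.points:
                fh.write(
                    f"{tr.track_id},{tr.replicate_id},{tr.group},"
                    f"{p.t!r},{p.x!r},{p.y!r}\n"
                )


def read_pilus_traces(path: str | Path, max_length: float = MAX_PILUS_LENGTH_UM) -> list[PilusTrace]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pilus trace table missing column(s): {missing}")
    traces = []
    for (cid, pid), sub in df.groupby(["cell_id", "pilus_id"], sort=False):
        samples = [(float(t), float(ln)) for t, ln in zip(sub["t_s"], sub["length_um"])]
        traces.append(PilusTrace(str(cid), str(pid), samples, max_length=max_length))
    return traces


def write_pilus_traces(traces: Iterable[PilusTrace], path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(TRACE_COLUMNS) + "\n")
        for tr in traces:
            for t, ln in tr.samples:
                fh.write(f"{tr.cell_id},{tr.pilus_id},{t!r},{ln!r}\n")


# ---------------------------------------------------------------------------
# TrackMate XML import (spot/edge subset only; features are recomputed here)


def _read_trackmate(
    path: Path, frame_interval: float | None, pixel_size: float | None
) -> Cohort:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed TrackMate XML {path}: {exc}") from exc
    root = tree.getroot()
    scale = 1.0 if pixel_size is None else float(pixel_size)

    spots: dict[str, TrackPoint] = {}
    for spot in root.iter("Spot"):
        sid = spot.get("ID")
        try:
            t = float(spot.get("POSITION_T"))
            x = float(spot.get("POSITION_X")) * scale
            y = float(spot.get("POSITION_Y")) * scale
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed Spot element ID={sid!r}: {exc}") from exc
        spots[sid] = TrackPoint(t=t, x=x, y=y)

    tracks: list[Track] = []
    for tm_track in root.iter("Track"):
        tid = tm_track.get("TRACK_ID", tm_track.get("name", str(len(tracks))))
        ids: set[str] = set()
        for edge in tm_track.iter("Edge"):
            src, dst = edge.get("SPOT_SOURCE_ID"), edge.get("SPOT_TARGET_ID")
            if src is None or dst is None:
                raise ValueError(f"Edge in track {tid!r} lacks source/target spot id")
            for sid in (src, dst):
                if sid not in spots:
                    raise ValueError(f"Edge in track {tid!r} references unknown spot {sid!r}")
                ids.add(sid)
        if not ids:
            continue
        pts = sorted((spots[i] for i in ids), key=lambda p: p.t)
        ts = np.array([p.t for p in pts])
        if np.any(np.diff(ts) <= 0):
            raise ValueError(f"track {tid!r}: non-monotone POSITION_T in XML")
        dt = frame_interval if frame_interval is not None else _infer_frame_interval(ts)
        tracks.append(
            Track(track_id=str(tid), replicate_id="rep1", group="imported",
                  points=pts, frame_interval=dt)
        )
    return Cohort(tracks=tracks)
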