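import numpy as np
import pytest

from pilitrack.io import Track, TrackPoint
from pilitrack.simulate import builtin_presets, simulate_cohort


def make_track(xy, dt=1.0, track_id="t0", replicate_id="rep1", group="G"):
    """Build a Track from a list of (x, y) sampled at consecutive frames."""
    pts = [TrackPoint(t=i * dt, x=float(x), y=float(y)) for i, (x, y) in enumerate(xy)]
    return Track(track_id=track_id, replicate_id=replicate_id, group=group,
                 points=pts, frame_interval=dt)


def random_track(rng, n=50, step_sd=0.5, gap_prob=0.0, dt=1.0, track_id="r0"):
    """Random-walk track, optionally with missing frames (gaps)."""
    pos = np.cumsum(rng.normal(0, step_sd, (n, 2)), axis=0)
    keep = np.ones(n, dtype=bool)
    if gap_prob > 0:
        keep[1:-1] = rng.random(n - 2) >= gap_prob
    pts = [TrackPoint(t=i * dt, x=float(p[0]), y=float(p[1]))
           for i, p in enumerate(pos) if keep[i]]
    return Track(track_id=track_id, replicate_id="rep1", group="G",
                 points=pts, frame_interval=dt)


@pytest.fixture(scope="session")
def presets():
    return builtin_presets()


@pytest.fixture(scope="session")
def wt_small(presets):
    """A small WT cohort shared across tests (40 tracks, 3 replicates)."""
    cohort, truths = simulate_cohort(presets["WT"], 40, 3, seed=11)
    return cohort, truths
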