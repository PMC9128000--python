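import numpy as np
import pandas as pd
import pytest

from foragedecomp.geometry import build_default_arena
from foragedecomp.tracking import CimarKey, Excursion, TrackingTable


@pytest.fixture(scope="session")
def layout():
    return build_default_arena()


def make_table(xy, fps=30.0, metadata=None, velocity=None):
    """TrackingTable from an (n, 2) coordinate array."""
    xy = np.asarray(xy, dtype=float)
    t = np.arange(len(xy)) / fps
    if velocity is None:
        step = np.linalg.norm(np.diff(xy, axis=0), axis=1)
        velocity = np.concatenate([[0.0], step * fps])
    df = pd.DataFrame({"time": t, "x": xy[:, 0], "y": xy[:, 1],
                       "velocity": velocity})
    return TrackingTable(frames=df, frame_rate=fps, metadata=metadata or {})


def make_excursion(xy, fps=30.0, velocity=None):
    """Excursion whose interior is xy[1:-1]."""
    table = make_table(xy, fps=fps, velocity=velocity)
    key = CimarKey(mouse="t", excursion=1, start_frame=0,
                   end_frame=len(xy) - 1)
    return Excursion(key=key, trajectory=table.frames, frame_rate=fps)
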