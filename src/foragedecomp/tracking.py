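"""Frame-level tracking tables, coordinate normalization, excursion segmentation.

A tracking session is a 30 frames/s table of (time, x, y, velocity) with the
mouse's zone membership.  Sessions from different arenas/cameras are brought
into a common coordinate frame by a landmark similarity (Procrustes)
transform, zeroed on the tunnel center.  Each session is then segmented into
round-trip home-base *excursions*: maximal stretches that start and end in the
In Tunnel zone with the whole interior on the platform.  Every excursion
carries a CIMAR key (mouse, excursion number, sex, age, genotype, phase).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import ArenaLayout, build_default_arena, in_tunnel_mask

__all__ = [
    "TrackingTable",
    "CimarKey",
    "Excursion",
    "FormatError",
    "DegeneracyError",
    "read_tracking",
    "procrustes_align",
    "segment_excursions",
]

REQUIRED_COLUMNS = ("time", "x", "y", "velocity")
DEFAULT_FRAME_RATE = 30.0


class FormatError(ValueError):
    """Input file violates the tracking-table contract."""


class DegeneracyError(ValueError):
    """Landmark configuration does not determine a similarity transform."""


@dataclass
class TrackingTable:
    """One session of frame-level tracking data.

    ``frames`` holds at least ``time, x, y, velocity``; ``metadata`` holds the
    session's design factors (mouse, sex, age, genotype, cross, phase).
    """

    frames: pd.DataFrame
    frame_rate: float = DEFAULT_FRAME_RATE
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in REQUIRED_COLUMNS if c not in self.frames.columns]
        if missing:
            raise FormatError(f"missing required column(s): {missing}")
        t = self.frames["time"].to_numpy(dtype=float)
        if len(t) > 1:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise FormatError("time must be strictly increasing")
            expected = 1.0 / self.frame_rate
            if np.any(np.abs(dt - expected) > 0.25 * expected):
                raise FormatError(
                    f"frame spacing deviates from 1/{self.frame_rate:g} s"
                )
        v = self.frames["velocity"].to_numpy(dtype=float)
        if np.nanmin(v, initial=0.0) < 0:
            raise FormatError("velocity must be non-negative")
        self.frames = self.frames.reset_index(drop=True)

    def __len__(self):
        return len(self.frames)

    @property
    def xy(self) -> np.ndarray:
        return self.frames[["x", "y"]].to_numpy(dtype=float)

    @property
    def n_missing(self) -> int:
        return int(self.frames[["x", "y"]].isna().any(axis=1).sum())


@dataclass(frozen=True)
class CimarKey:
    """Concise per-excursion identity key with frame coordinates."""

    mouse: str
    excursion: int
    sex: str = "unknown"
    age: str = "adult"
    genotype: str = "wildtype"
    cross: str = "unknown"
    phase: str = "exploration"
    start_frame: int = 0
    end_frame: int = 0

    def __post_init__(self):
        if self.end_frame <= self.start_frame:
            raise ValueError("end frame must exceed start frame")

    def to_string(self) -> str:
        return (
            f"{self.mouse}|E{self.excursion}|{self.sex}|{self.age}|"
            f"{self.genotype}|{self.phase}|{self.start_frame}-{self.end_frame}"
        )

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class Excursion:
    """One round trip: tunnel -> platform -> tunnel.

    ``trajectory`` includes the bounding In-Tunnel frame on each side; the
    interior frames (all on the platform) are ``trajectory.iloc[1:-1]``.
    """

    key: CimarKey
    trajectory: pd.DataFrame
    frame_rate: float = DEFAULT_FRAME_RATE

    @property
    def interior(self) -> pd.DataFrame:
        return self.trajectory.iloc[1:-1]

    @property
    def duration(self) -> float:
        """Interior duration in seconds."""
        return len(self.interior) / self.frame_rate


def read_tracking(path, metadata: dict | None = None,
                  frame_rate: float = DEFAULT_FRAME_RATE) -> TrackingTable:
    """Read a delimited tracking export (CSV or TSV) into a TrackingTable.

    The header must name ``time, x, y, velocity`` columns; extra columns
    (zone flags from the tracking software) are carried through untouched.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # noqa: BLE001 - surface as a format error
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    df.columns = [str(c).strip().lower() for c in df.columns]
    return TrackingTable(frames=df, frame_rate=frame_rate,
                         metadata=dict(metadata or {}))


# --- Procrustes normalization ----------------------------------------------

def _similarity_transform(src: np.ndarray, dst: np.ndarray):
    """Least-squares similarity transform (Umeyama): dst ~ s * R @ src + t."""
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise DegeneracyError("landmark arrays must be matching (n, 2)")
    n = src.shape[0]
    if n < 3:
        raise DegeneracyError("need at least 3 landmark pairs")
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    sc, dc = src - mu_s, dst - mu_d
    var_s = (sc**2).sum() / n
    if var_s < 1e-12:
        raise DegeneracyError("landmarks are coincident")
    # collinearity check: rank of centered source
    if np.linalg.matrix_rank(sc, tol=1e-9 * np.abs(sc).max()) < 2:
        raise DegeneracyError("landmarks are collinear")
    cov = dc.T @ sc / n
    U, D, Vt = np.linalg.svd(cov)
    S = np.eye(2)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        S[1, 1] = -1.0
    R = U @ S @ Vt
    s = np.trace(np.diag(D) @ S) / var_s
    t = mu_d - s * R @ mu_s
    return s, R, t


def procrustes_align(table: TrackingTable,
                     landmarks_observed,
                     landmarks_reference,
                     tunnel_center=(0.0, 0.0)) -> TrackingTable:
    """Map a session into the reference frame and zero it on the tunnel.

    Fits the similarity transform (rotation, uniform scale, translation)
    minimizing squared landmark error, applies it to every frame, and finally
    subtracts the reference-frame ``tunnel_center`` so the tunnel maps to the
    origin.  Velocities are rescaled by the recovered scale factor.
    """
    s, R, t = _similarity_transform(landmarks_observed, landmarks_reference)
    xy = table.xy
    new_xy = (s * (R @ xy.T)).T + t - np.asarray(tunnel_center, dtype=float)
    frames = table.frames.copy()
    frames["x"], frames["y"] = new_xy[:, 0], new_xy[:, 1]
    frames["velocity"] = frames["velocity"].to_numpy(dtype=float) * s
    return TrackingTable(frames=frames, frame_rate=table.frame_rate,
                         metadata=dict(table.metadata))


# --- Excursion segmentation -------------------------------------------------

def _interpolate_gaps(frames: pd.DataFrame, max_gap: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Linearly fill coordinate gaps of <= max_gap frames; flag longer ones."""
    frames = frames.copy()
    bad = frames[["x", "y"]].isna().any(axis=1).to_numpy()
    barrier = np.zeros(len(frames), dtype=bool)
    if bad.any():
        idx = np.flatnonzero(bad)
        # split into consecutive runs
        runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        for run in runs:
            if len(run) <= max_gap:
                continue
            barrier[run] = True
        for col in ("x", "y", "velocity"):
            filled = frames[col].interpolate(limit_area="inside")
            frames[col] = filled
        # anything still NaN (edges, long gaps) is a barrier
        barrier |= frames[["x", "y"]].isna().any(axis=1).to_numpy()
    return frames, barrier


def segment_excursions(table: TrackingTable,
                       window: tuple[float, float] = (0.0, 1500.0),
                       layout: ArenaLayout | None = None,
                       recompute_zones: bool = True,
                       max_gap: int = 5) -> list[Excursion]:
    """Segment a session into round-trip home-base excursions.

    An excursion begins when the mouse leaves the In Tunnel zone and ends when
    it next returns to it; the bounding In-Tunnel frame on each side is kept
    with the slice.  A trip still open at the window end is discarded.
    Coordinate dropouts of at most ``max_gap`` frames are linearly
    interpolated; longer dropouts invalidate any excursion spanning them.

    With ``recompute_zones`` (default), In-Tunnel membership is derived from
    ``layout``; otherwise an ``in_tunnel`` column must be present.
    """
    layout = layout or build_default_arena()
    t = table.frames["time"].to_numpy(dtype=float)
    in_window = (t >= window[0]) & (t <= window[1])
    frames, barrier = _interpolate_gaps(table.frames, max_gap)

    if recompute_zones:
        xy = frames[["x", "y"]].to_numpy(dtype=float)
        ok = ~np.isnan(xy).any(axis=1)
        tunnel = np.zeros(len(frames), dtype=bool)
        tunnel[ok] = in_tunnel_mask(xy[ok], layout)
    else:
        if "in_tunnel" not in frames.columns:
            raise FormatError("recompute_zones=False requires an in_tunnel column")
        tunnel = frames["in_tunnel"].astype(bool).to_numpy()

    md = table.metadata
    excursions: list[Excursion] = []
    number = 0
    idx = np.flatnonzero(in_window)
    if len(idx) == 0:
        return excursions
    i = idx[0]
    last = idx[-1]
    while i <= last:
        if not tunnel[i]:
            i += 1
            continue
        # find exit from tunnel
        j = i
        while j + 1 <= last and tunnel[j + 1]:
            j += 1
        if j == last:
            break
        # j is last tunnel frame before an exit; find return
        k = j + 1
        while k <= last and not tunnel[k]:
            k += 1
        if k > last:
            break  # unterminated trip at window end: dropped
        if not barrier[j:k + 1].any():
            number += 1
            key = CimarKey(
                mouse=str(md.get("mouse", "m0")),
                excursion=number,
                sex=str(md.get("sex", "unknown")),
                age=str(md.get("age", "adult")),
                genotype=str(md.get("genotype", "wildtype")),
                cross=str(md.get("cross", "unknown")),
                phase=str(md.get("phase", "exploration")),
                start_frame=int(j),
                end_frame=int(k),
            )
            excursions.append(Excursion(
                key=key,
                trajectory=frames.iloc[j:k + 1].reset_index(drop=True),
                frame_rate=table.frame_rate,
            ))
        i = k
    return excursions


def excursion_index(excursions: list[Excursion]) -> pd.DataFrame:
    """Tabulate CIMAR keys for an excursion list (CSV-ready)."""
    return pd.DataFrame([e.key.as_dict() for e in excursions])
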