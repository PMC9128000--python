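"""Per-excursion behavioral measures, keystone normalization, scaling.

Every excursion is described by a battery of named measures covering shape,
frequency, order and location statistics of the x/y trajectory, zone visit
counts and normalized durations, latencies, velocity statistics, and velocity
bouts.  Measures are computed on the excursion interior (platform frames).

Velocity classes use half-open thresholds: slow v <= 5, medium 5 < v <= 15,
fast v > 15 (cm/s).  A velocity *bout* is a maximal same-class run longer
than 3 frames.

Keystone features (per-mouse summary outcomes) are normalized against two
anchors: time/visit/consumption features divided by the total time in arena
(TTA), pot latencies shifted by the latency to enter the platform (LEP).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import ArenaLayout, build_default_arena, zone_flags_table
from .tracking import Excursion

__all__ = [
    "VelocityClass",
    "classify_velocity",
    "classify_velocity_array",
    "count_velocity_bouts",
    "compute_measures",
    "measure_names",
    "measure_matrix",
    "normalize_keystones",
    "scale_matrix",
    "MeasureMatrix",
]

SLOW_MAX = 5.0
MEDIUM_MAX = 15.0
MIN_BOUT_FRAMES = 4  # runs longer than 3 frames count as a bout

CLASSES = ("slow", "medium", "fast")


class VelocityClass:
    SLOW = "slow"
    MEDIUM = "medium"
    FAST = "fast"


def classify_velocity(v: float) -> str:
    """Classify a speed (cm/s) as slow (<=5), medium (>5, <=15) or fast (>15)."""
    if v < 0:
        raise ValueError("velocity must be non-negative")
    if v <= SLOW_MAX:
        return VelocityClass.SLOW
    if v <= MEDIUM_MAX:
        return VelocityClass.MEDIUM
    return VelocityClass.FAST


def classify_velocity_array(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise ValueError("velocity must be non-negative")
    out = np.full(v.shape, VelocityClass.FAST, dtype=object)
    out[v <= MEDIUM_MAX] = VelocityClass.MEDIUM
    out[v <= SLOW_MAX] = VelocityClass.SLOW
    return out


def count_velocity_bouts(classes) -> dict:
    """Count velocity bouts: maximal same-class runs of >= 4 frames.

    Returns ``{class: {"count": n, "frames": total_frames}}`` over the three
    classes; shorter runs are ignored entirely.
    """
    classes = list(classes)
    if not classes:
        raise ValueError("class sequence must be non-empty")
    out = {c: {"count": 0, "frames": 0} for c in CLASSES}
    run_val, run_len = classes[0], 1
    for c in classes[1:] + [None]:
        if c == run_val:
            run_len += 1
            continue
        if run_len >= MIN_BOUT_FRAMES:
            out[run_val]["count"] += 1
            out[run_val]["frames"] += run_len
        run_val, run_len = c, 1
    return out


def _visits(mask: np.ndarray, debounce: int = 5) -> int:
    """Number of entries into a zone (start inside counts as one).

    Boundary flicker is debounced: an exit shorter than ``debounce`` frames
    does not end the visit (tracking software applies a similar filter).
    """
    if mask.size == 0:
        return 0
    visits = 0
    inside = False
    outside_run = debounce  # so the first entry always counts
    for m in mask:
        if m:
            if not inside and outside_run >= debounce:
                visits += 1
            inside = True
            outside_run = 0
        else:
            if inside:
                outside_run = 1
                inside = False
            else:
                outside_run += 1
    return visits


#: latency recorded for a zone the excursion never visits (s).  A fixed cap
#: keeps the measure constant across non-visiting excursions; tying it to the
#: excursion duration instead would alias duration variance into latencies.
LATENCY_CAP = 300.0


def _latency(mask: np.ndarray, fps: float) -> float:
    """Seconds from excursion start to first frame in the zone."""
    hits = np.flatnonzero(mask)
    return float(hits[0]) / fps if hits.size else LATENCY_CAP


def compute_measures(excursion: Excursion,
                     layout: ArenaLayout | None = None) -> dict:
    """Compute the full named measure vector for one excursion.

    Deterministic: identical trajectories give identical vectors.  Raises on
    an empty interior.
    """
    layout = layout or build_default_arena()
    interior = excursion.interior
    if len(interior) == 0:
        raise ValueError("excursion has no interior frames")
    fps = excursion.frame_rate
    x = interior["x"].to_numpy(dtype=float)
    y = interior["y"].to_numpy(dtype=float)
    v = interior["velocity"].to_numpy(dtype=float)
    n = len(x)
    duration = n / fps
    r = np.hypot(x, y)
    theta = np.arctan2(y, x)

    m: dict[str, float] = {}
    # shape / location statistics of x and y
    for name, arr in (("x", x), ("y", y)):
        m[f"{name}.min"] = float(arr.min())
        m[f"{name}.max"] = float(arr.max())
        m[f"{name}.mean"] = float(arr.mean())
        m[f"{name}.median"] = float(np.median(arr))
        m[f"{name}.sd"] = float(arr.std(ddof=0))
        m[f"{name}.range"] = float(arr.max() - arr.min())
    # radial statistics
    m["r.min"] = float(r.min())
    m["r.max"] = float(r.max())
    m["r.mean"] = float(r.mean())
    m["r.sd"] = float(r.std(ddof=0))
    # angular placement: radius-weighted mean direction components.  These
    # go smoothly to 0 for angularly symmetric paths instead of flipping
    # sign the way a normalized centroid direction (or per-frame angles
    # near the origin) would.
    r_mean = r.mean()
    m["angle.mean.cos"] = float(x.mean() / r_mean) if r_mean > 1e-9 else 0.0
    m["angle.mean.sin"] = float(y.mean() / r_mean) if r_mean > 1e-9 else 0.0

    # order statistics: stepwise heading changes and path tortuosity
    dx, dy = np.diff(x), np.diff(y)
    steps = np.hypot(dx, dy)
    total_dist = float(steps.sum())
    m["distance.total"] = total_dist
    headings = np.arctan2(dy[steps > 1e-12], dx[steps > 1e-12])
    if headings.size >= 2:
        turns = np.abs(np.angle(np.exp(1j * np.diff(headings))))
        m["turn.mean"] = float(turns.mean())
        m["turn.sum"] = float(turns.sum())
    else:
        m["turn.mean"] = 0.0
        m["turn.sum"] = 0.0
    extent = float(r.max())
    m["tortuosity"] = total_dist / extent if extent > 1e-12 else 0.0

    # timing / velocity
    m["duration"] = duration
    # no velocity median: per-frame speed distributions are multimodal
    # (stops vs runs), where a median is a knife-edge statistic
    m["vel.mean"] = float(v.mean())
    m["vel.sd"] = float(v.std(ddof=0))
    m["vel.max"] = float(v.max())

    # velocity classes and bouts
    classes = classify_velocity_array(v)
    for c in CLASSES:
        m[f"frac.{c}"] = float((classes == c).mean())
    bouts = count_velocity_bouts(classes)
    for c in CLASSES:
        m[f"bouts.{c}.count"] = float(bouts[c]["count"])
        m[f"bouts.{c}.dur"] = bouts[c]["frames"] / fps

    # zone occupancy, visits and latencies
    flags = zone_flags_table(np.column_stack([x, y]), layout)
    for zone in ("center", "intermediate", "wall",
                 "pot1", "pot2", "pot3", "pot4", "tunnel_zone"):
        mask = flags[zone]
        m[f"time.{zone}"] = float(mask.mean())  # fraction of interior time
        m[f"visits.{zone}"] = float(_visits(mask))
    for zone in ("center", "pot1", "pot2", "pot3", "pot4"):
        m[f"latency.{zone}"] = _latency(flags[zone], fps)
    # first pot visited (0 if none), a simple order statistic
    first_pot = 0
    best = np.inf
    for i in range(1, 5):
        hits = np.flatnonzero(flags[f"pot{i}"])
        if hits.size and hits[0] < best:
            best, first_pot = hits[0], i
    m["first.pot"] = float(first_pot)
    m["sectors.visited"] = float(len(np.unique(flags["sector"])))

    return m


def measure_names(layout: ArenaLayout | None = None) -> list[str]:
    """Stable identifiers of the default measure registry (>= 57 measures)."""
    from .synth import _probe_excursion  # tiny deterministic excursion
    return list(compute_measures(_probe_excursion(), layout).keys())


def measure_matrix(excursions, layout: ArenaLayout | None = None) -> pd.DataFrame:
    """Excursions x measures table, indexed by CIMAR strings."""
    layout = layout or build_default_arena()
    rows = {e.key.to_string(): compute_measures(e, layout) for e in excursions}
    return pd.DataFrame.from_dict(rows, orient="index")


# --- scaling ----------------------------------------------------------------

@dataclass
class MeasureMatrix:
    """Scaled excursions x measures table with its scaling state."""

    data: pd.DataFrame
    center: pd.Series | None = None
    spread: pd.Series | None = None
    constant_columns: list = field(default_factory=list)

    @property
    def scaled(self) -> bool:
        return self.center is not None


def scale_matrix(data) -> MeasureMatrix:
    """Z-score each measure across excursions (constant columns -> 0, flagged).

    Idempotent on already-scaled data.  Requires >= 2 excursions.
    """
    if isinstance(data, MeasureMatrix):
        data = data.data
    if len(data) < 2:
        raise ValueError("scaling requires at least 2 excursions")
    center = data.mean(axis=0)
    spread = data.std(axis=0, ddof=1)
    constant = spread.index[spread < 1e-12].tolist()
    safe = spread.replace(0.0, 1.0)
    safe[constant] = 1.0
    scaled = (data - center) / safe
    scaled[constant] = 0.0
    return MeasureMatrix(data=scaled, center=center, spread=spread,
                         constant_columns=constant)


# --- keystone features ------------------------------------------------------

#: column-name rule prefixes for keystone normalization
TTA_PREFIXES = ("time_", "visits_", "sand_", "food_", "tfc", "td")
LEP_PREFIXES = ("latency_pot",)
PASSTHROUGH_PREFIXES = ("lcae", "pct_")
EXCLUDED = ("time_platform", "time_tunnel")


def _bin_suffix(col: str) -> str | None:
    """'time_pot2_bin3' -> 'bin3' (per-5-min-bin measures), else None."""
    tail = col.rsplit("_", 1)[-1]
    return tail if tail.startswith("bin") else None


def normalize_keystones(raw: pd.DataFrame,
                        tta_col: str = "tta",
                        lep_col: str = "lep") -> pd.DataFrame:
    """Normalize a per-mouse keystone table against its anchors.

    Zone-time, visit, sand and food columns are divided by TTA (per-bin
    columns, suffixed ``_binK``, by that bin's TTA column ``tta_binK``); pot
    latencies have LEP subtracted; LCAE and percentage columns pass through;
    platform and tunnel time are excluded as redundant with TTA.  Rows with
    TTA == 0 are dropped and reported via the ``excluded_mice`` attribute.
    """
    df = raw.copy()
    df.columns = [str(c).lower() for c in df.columns]
    if tta_col not in df.columns:
        raise ValueError(f"keystone table lacks anchor column {tta_col!r}")
    bad = df[tta_col] <= 0
    excluded_mice = df.index[bad].tolist()
    df = df.loc[~bad]

    out = pd.DataFrame(index=df.index)
    for col in df.columns:
        if col in (tta_col, lep_col) or col.startswith("tta_"):
            continue
        if col in EXCLUDED:
            continue
        if col.startswith(LEP_PREFIXES):
            if lep_col not in df.columns:
                raise ValueError(f"latency column {col!r} needs anchor {lep_col!r}")
            out[col] = df[col] - df[lep_col]
        elif col.startswith(PASSTHROUGH_PREFIXES):
            out[col] = df[col]
        elif col.startswith(TTA_PREFIXES):
            b = _bin_suffix(col)
            anchor = f"tta_{b}" if b and f"tta_{b}" in df.columns else tta_col
            out[col] = df[col] / df[anchor]
        else:
            out[col] = df[col]
    out.attrs["excluded_mice"] = excluded_mice
    return out
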