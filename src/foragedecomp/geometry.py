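"""Foraging arena geometry and tracking zones.

The arena is a 35 cm diameter circular platform entered from below through a
home tunnel.  Five 5.5 cm holes sit on a concentric "intermediate" circle: one
holds the tunnel, four hold sand pots.  The platform is divided into three
concentric rings (Center, Intermediate, Wall) and five angular sectors whose
boundaries are the midpoints between adjacent holes.  Additional circular
zones surround each pot and the tunnel entry.

All lengths are centimeters, arena-centered coordinates.  Zone assignment is
deterministic: points exactly on a boundary belong to the inner region
(half-open convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "ArenaLayout",
    "ZoneSet",
    "OutOfArenaError",
    "build_default_arena",
    "locate",
    "in_tunnel_mask",
    "layout_to_yaml",
    "layout_from_yaml",
]


class OutOfArenaError(ValueError):
    """Point lies outside the arena wall and outside the tunnel geometry."""


@dataclass(frozen=True)
class ArenaLayout:
    """Dimensioned model of the foraging arena.

    Parameters
    ----------
    arena_radius:
        Radius of the circular platform (cm).  The arena is 35 cm across.
    pot_radius:
        Radius of each sand pot (cm); pots sit in 5.5 cm diameter holes.
    pot_zone_factor:
        Pot zones extend ``pot_zone_factor`` times the pot radius.
    intermediate_outer_radius:
        Radial distance of the hole centers; also the outer radius of the
        Intermediate ring.  The Center ring radius is half of it.
    tunnel_angle_deg:
        Angular position of the tunnel hole (degrees, mathematical
        convention).  The four pots follow at 72 degree spacing.
    in_tunnel_radius:
        Radius of the In Tunnel zone around the tunnel center: a mouse within
        it is considered off the platform (down the hole / in the home cage).
    """

    arena_radius: float = 17.5
    pot_radius: float = 2.75
    pot_zone_factor: float = 1.7
    intermediate_outer_radius: float = 12.0
    tunnel_angle_deg: float = 270.0
    in_tunnel_radius: float = 1.0

    # derived, filled in __post_init__
    pot_positions: tuple = field(default=None, repr=False)
    tunnel_center: tuple = field(default=None, repr=False)
    platform_holes: tuple = field(default=None, repr=False)
    sector_boundaries: tuple = field(default=None, repr=False)

    def __post_init__(self):
        r = self.intermediate_outer_radius
        angles = [math.radians(self.tunnel_angle_deg + 72.0 * k) for k in range(5)]
        holes = tuple((r * math.cos(a), r * math.sin(a)) for a in angles)
        object.__setattr__(self, "platform_holes", holes)
        object.__setattr__(self, "tunnel_center", holes[0])
        object.__setattr__(self, "pot_positions", holes[1:])
        # sector boundaries at midpoints between adjacent holes
        bounds = tuple(
            math.radians(self.tunnel_angle_deg + 36.0 + 72.0 * k) % (2 * math.pi)
            for k in range(5)
        )
        object.__setattr__(self, "sector_boundaries", bounds)
        self._validate()

    def _validate(self):
        if not 0 < self.intermediate_outer_radius < self.arena_radius:
            raise ValueError("hole circle must lie strictly inside the arena wall")
        if self.pot_zone_factor <= 0 or self.pot_radius <= 0:
            raise ValueError("pot dimensions must be positive")

    @property
    def center_radius(self) -> float:
        """Center-ring radius: half the Intermediate ring's outer radius."""
        return self.intermediate_outer_radius / 2.0

    @property
    def pot_zone_radius(self) -> float:
        return self.pot_zone_factor * self.pot_radius

    @property
    def tunnel_zone_radius(self) -> float:
        """Tunnel Zone shares the Pot-zone radius."""
        return self.pot_zone_radius

    @property
    def tunnel_entry_radius(self) -> float:
        """Tunnel Entry zone aligns with the 5.5 cm entry hole."""
        return self.pot_radius


@dataclass(frozen=True)
class ZoneSet:
    """Zone membership flags for a single tracked point."""

    center: bool
    intermediate: bool
    wall: bool
    pots: tuple  # 4 booleans, pot zones 1..4
    tunnel_entry: bool
    in_tunnel: bool
    tunnel_zone: bool
    sector: int  # 1..5

    @property
    def on_platform(self) -> bool:
        return self.center or self.intermediate or self.wall

    @property
    def ring(self) -> str:
        if self.in_tunnel:
            return "in_tunnel"
        if self.center:
            return "center"
        if self.intermediate:
            return "intermediate"
        return "wall"


def build_default_arena(**overrides) -> ArenaLayout:
    """Return the study's arena: 35 cm diameter, 5.5 cm pots, pot zones 1.7x."""
    return ArenaLayout(**overrides)


def locate(point, layout: ArenaLayout) -> ZoneSet:
    """Assign a single (x, y) point (cm) to its arena zones.

    Raises
    ------
    OutOfArenaError
        If the point lies beyond the arena wall.
    """
    x, y = float(point[0]), float(point[1])
    r = math.hypot(x, y)
    if r > layout.arena_radius:
        raise OutOfArenaError(f"point ({x:.2f}, {y:.2f}) lies outside the arena wall")

    tx, ty = layout.tunnel_center
    d_tunnel = math.hypot(x - tx, y - ty)
    in_tunnel = d_tunnel <= layout.in_tunnel_radius

    center = intermediate = wall = False
    if not in_tunnel:
        if r <= layout.center_radius:
            center = True
        elif r <= layout.intermediate_outer_radius:
            intermediate = True
        else:
            wall = True

    pots = tuple(
        math.hypot(x - px, y - py) <= layout.pot_zone_radius
        for (px, py) in layout.pot_positions
    )
    tunnel_entry = d_tunnel <= layout.tunnel_entry_radius
    tunnel_zone = d_tunnel <= layout.tunnel_zone_radius

    angle = math.atan2(y, x)
    sector = _sector_zone_index(angle, layout)

    return ZoneSet(
        center=center,
        intermediate=intermediate,
        wall=wall,
        pots=pots,
        tunnel_entry=tunnel_entry,
        in_tunnel=in_tunnel,
        tunnel_zone=tunnel_zone,
        sector=sector,
    )


def _sector_zone_index(angle: float, layout: ArenaLayout) -> int:
    """Sector 1 contains the tunnel hole; sectors increase with angle."""
    # offset so that sector boundaries become multiples of 72 degrees
    first = math.radians(layout.tunnel_angle_deg - 36.0)
    rel = (angle - first) % (2 * math.pi)
    return int(rel // math.radians(72.0)) + 1


def in_tunnel_mask(xy: np.ndarray, layout: ArenaLayout) -> np.ndarray:
    """Vectorized In-Tunnel test for an (n, 2) coordinate array."""
    xy = np.asarray(xy, dtype=float)
    tx, ty = layout.tunnel_center
    d = np.hypot(xy[:, 0] - tx, xy[:, 1] - ty)
    return d <= layout.in_tunnel_radius


def zone_flags_table(xy: np.ndarray, layout: ArenaLayout) -> dict:
    """Vectorized zone flags for an (n, 2) coordinate array.

    Returns a dict of boolean / integer arrays mirroring :class:`ZoneSet`.
    Points outside the wall raise :class:`OutOfArenaError`.
    """
    xy = np.asarray(xy, dtype=float)
    r = np.hypot(xy[:, 0], xy[:, 1])
    if np.any(r > layout.arena_radius + 1e-9):
        raise OutOfArenaError("trajectory leaves the arena wall")
    tx, ty = layout.tunnel_center
    d_tunnel = np.hypot(xy[:, 0] - tx, xy[:, 1] - ty)
    in_tunnel = d_tunnel <= layout.in_tunnel_radius
    center = (~in_tunnel) & (r <= layout.center_radius)
    intermediate = (~in_tunnel) & (~center) & (r <= layout.intermediate_outer_radius)
    wall = (~in_tunnel) & (~center) & (~intermediate)
    flags = {
        "in_tunnel": in_tunnel,
        "center": center,
        "intermediate": intermediate,
        "wall": wall,
        "tunnel_entry": d_tunnel <= layout.tunnel_entry_radius,
        "tunnel_zone": d_tunnel <= layout.tunnel_zone_radius,
    }
    for i, (px, py) in enumerate(layout.pot_positions, start=1):
        flags[f"pot{i}"] = np.hypot(xy[:, 0] - px, xy[:, 1] - py) <= layout.pot_zone_radius
    first = math.radians(layout.tunnel_angle_deg - 36.0)
    rel = (np.arctan2(xy[:, 1], xy[:, 0]) - first) % (2 * math.pi)
    flags["sector"] = (rel // math.radians(72.0)).astype(int) + 1
    return flags


# --- YAML configuration -----------------------------------------------------

_CONFIG_FIELDS = (
    "arena_radius",
    "pot_radius",
    "pot_zone_factor",
    "intermediate_outer_radius",
    "tunnel_angle_deg",
    "in_tunnel_radius",
)


def layout_to_yaml(layout: ArenaLayout) -> str:
    """Serialize the layout as an ``arena:`` YAML block (cm, degrees)."""
    return yaml.safe_dump(
        {"arena": {k: float(getattr(layout, k)) for k in _CONFIG_FIELDS}},
        sort_keys=False,
    )


def layout_from_yaml(text: str) -> ArenaLayout:
    cfg = yaml.safe_load(text)["arena"]
    unknown = set(cfg) - set(_CONFIG_FIELDS)
    if unknown:
        raise ValueError(f"unknown arena config keys: {sorted(unknown)}")
    return ArenaLayout(**cfg)
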