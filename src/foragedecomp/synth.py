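"""Synthetic foraging data with planted ground truth.

Generates every input the pipeline consumes so all stages are testable
without real tracking data:

* 30 frames/s trajectories in the 35 cm arena, built from a library of six
  excursion *templates* (direct-to-food, loop-explore, wall-follow,
  dig-at-pot, center-dart, short-peek) that differ across several measure
  families.  Trajectories are piecewise-linear between arena waypoints with
  per-segment speeds drawn inside a target velocity-class interval, so
  velocity bouts are classifiable by construction.
* cohorts with a genotype x cross x sex design: per-mouse module counts are
  Poisson with per-cell rates (planted genotype x cross interactions), and
  per-mouse module sequences follow sex-specific transition chains;
* allelic expression replicates with a planted coupling between the focal
  gene's imprinting signal and one marker category.

All randomness flows from a single seed through numpy SeedSequence spawning,
so each mouse is regenerable in isolation.  Truth records carry every
planted parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .allelic import AllelicExpressionMatrix, MarkerSet
from .geometry import ArenaLayout, build_default_arena
from .tracking import CimarKey, Excursion, TrackingTable

__all__ = [
    "ModuleTemplate",
    "CohortDesign",
    "default_templates",
    "generate_excursion",
    "generate_session",
    "generate_cohort",
    "generate_module_counts",
    "generate_allelic_dataset",
]

FPS = 30.0

# velocity-class sampling intervals (cm/s), inside the slow/medium/fast bands
_CLASS_SPEED = {"slow": (2.0, 4.2), "medium": (7.0, 12.0), "fast": (17.0, 24.0)}


@dataclass(frozen=True)
class ModuleTemplate:
    """Parametric excursion archetype.

    ``path`` is a sequence of (waypoint, velocity_class) pairs; waypoints are
    symbolic arena anchors resolved against the layout.  ``dwells`` maps a
    path position to extra slow-wiggle frames spent there.
    """

    template_id: int
    name: str
    path: tuple  # ((anchor, class), ...)
    dwells: dict = field(default_factory=dict)  # path index -> frames
    waypoint_jitter: float = 0.5  # cm, per-excursion anchor displacement
    frame_jitter: float = 0.005  # cm, per-frame positional noise


def _anchor_xy(anchor: str, layout: ArenaLayout) -> np.ndarray:
    """Resolve a symbolic waypoint to coordinates."""
    tx, ty = layout.tunnel_center
    if anchor == "tunnel":
        return np.array([tx, ty])
    if anchor == "tunnel_exit":
        # just onto the platform beside the tunnel: outside the tunnel zone,
        # mid-Intermediate ring, clear of the Center-ring boundary
        ang = np.radians(layout.tunnel_angle_deg + 25.0)
        r = 0.75 * layout.intermediate_outer_radius
        return np.array([r * np.cos(ang), r * np.sin(ang)])
    if anchor == "center":
        return np.array([0.0, 0.0])
    if anchor.startswith("pot"):
        inset = anchor.endswith("_in")
        num = int(anchor[3:-3] if inset else anchor[3:])
        p = np.array(layout.pot_positions[num - 1])
        if inset:
            # pulled 1.5 cm toward the arena center: inside the pot zone but
            # clear of the intermediate/wall ring boundary the pots sit on
            p = p * (1 - 1.5 / np.linalg.norm(p))
        return p
    if anchor.startswith("wall@"):
        ang = np.radians(float(anchor.split("@")[1]))
        r = layout.arena_radius - 1.5
        return np.array([r * np.cos(ang), r * np.sin(ang)])
    raise ValueError(f"unknown waypoint anchor {anchor!r}")


def default_templates() -> list[ModuleTemplate]:
    """Six archetypes differing in location, shape, velocity and zone usage."""
    return [
        ModuleTemplate(1, "direct_to_food",
                       (("tunnel", "fast"), ("pot4_in", "fast"),
                        ("tunnel", "medium")),
                       dwells={1: 45}),
        ModuleTemplate(2, "loop_explore",
                       (("tunnel", "medium"), ("pot1_in", "medium"),
                        ("center", "medium"), ("pot2_in", "medium"),
                        ("pot3_in", "medium"), ("tunnel", "medium"))),
        ModuleTemplate(3, "wall_follow",
                       (("tunnel", "medium"),)
                       + tuple((f"wall@{a}", "fast")
                               for a in (240, 210, 180, 150, 120, 90,
                                         60, 30, 0, 330, 300))
                       + (("tunnel", "medium"),)),
        ModuleTemplate(4, "dig_at_pot",
                       (("tunnel", "medium"), ("pot2_in", "medium"),
                        ("tunnel", "slow")),
                       dwells={1: 150}),
        ModuleTemplate(5, "center_dart",
                       (("tunnel", "fast"), ("center", "fast"),
                        ("tunnel", "fast")),
                       dwells={1: 30}),
        ModuleTemplate(6, "short_peek",
                       (("tunnel", "slow"), ("tunnel_exit", "slow"),
                        ("tunnel", "slow")),
                       dwells={1: 20}),
    ]


def _clip_to_arena(xy: np.ndarray, layout: ArenaLayout) -> np.ndarray:
    r = np.hypot(xy[:, 0], xy[:, 1])
    lim = layout.arena_radius - 0.05
    over = r > lim
    if over.any():
        xy[over] *= (lim / r[over])[:, None]
    return xy


def generate_excursion(template: ModuleTemplate, layout: ArenaLayout,
                       rng: np.random.Generator,
                       jitter: bool = True) -> np.ndarray:
    """Frame coordinates of one round trip, tunnel to tunnel (n, 2)."""
    wj = template.waypoint_jitter if jitter else 0.0
    fj = template.frame_jitter if jitter else 0.0
    pts = []
    for i, (anchor, _cls) in enumerate(template.path):
        p = _anchor_xy(anchor, layout)
        if anchor != "tunnel" and wj > 0:
            p = p + rng.normal(0.0, wj, size=2)
        pts.append(p)

    frames = [np.array(layout.tunnel_center)]
    dt = 1.0 / FPS
    for i in range(1, len(pts)):
        _, cls = template.path[i]
        lo, hi = _CLASS_SPEED[cls]
        speed = rng.uniform(lo, hi) if jitter else 0.5 * (lo + hi)
        a, b = frames[-1], pts[i]  # continue from the actual last position
        seg = np.linalg.norm(b - a)
        n_steps = max(int(np.ceil(seg / (speed * dt))), 1)
        for s in range(1, n_steps + 1):
            frames.append(a + (b - a) * (s / n_steps))
        dwell = template.dwells.get(i, 0)
        if dwell:
            # mean-reverting slow wiggle: stays near the waypoint, speeds in
            # the slow band (~0.08 cm/frame ~ 2.4 cm/s)
            step = 0.08
            anchor_pos = frames[-1].copy()
            pos = anchor_pos.copy()
            for _ in range(dwell):
                direction = rng.normal(size=2) if jitter else np.array([1.0, 0.0])
                direction = direction + 0.6 * (anchor_pos - pos) / step
                norm = np.linalg.norm(direction)
                pos = pos + step * direction / (norm if norm > 0 else 1.0)
                frames.append(pos.copy())
    xy = np.array(frames)
    if fj > 0:
        xy[1:-1] += rng.normal(0.0, fj, size=(len(xy) - 2, 2))
    return _clip_to_arena(xy, layout)


def _frames_to_table(xy: np.ndarray, metadata: dict) -> TrackingTable:
    t = np.arange(len(xy)) / FPS
    step = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    vel = np.concatenate([[0.0], step * FPS])
    df = pd.DataFrame({"time": t, "x": xy[:, 0], "y": xy[:, 1],
                       "velocity": vel})
    return TrackingTable(frames=df, frame_rate=FPS, metadata=metadata)


def generate_session(templates, sequence, layout: ArenaLayout | None = None,
                     seed=None, metadata: dict | None = None,
                     tunnel_frames: int = 15) -> tuple[TrackingTable, list]:
    """One mouse session: tunnel bouts alternating with templated excursions.

    ``sequence`` is the ordered list of template ids expressed.  Returns the
    tracking table and the planted template id per excursion (ground truth).
    """
    layout = layout or build_default_arena()
    rng = np.random.default_rng(seed)
    by_id = {t.template_id: t for t in templates}
    tunnel = np.array(layout.tunnel_center)
    blocks = [np.tile(tunnel, (tunnel_frames, 1))]
    truth = []
    for tid in sequence:
        xy = generate_excursion(by_id[tid], layout, rng)
        blocks.append(xy[1:-1])  # interior
        blocks.append(np.tile(tunnel, (tunnel_frames, 1)))
        truth.append(tid)
    xy = np.vstack(blocks)
    return _frames_to_table(xy, dict(metadata or {})), truth


def _probe_excursion() -> Excursion:
    """Tiny deterministic excursion used to enumerate the measure registry."""
    layout = build_default_arena()
    xy = generate_excursion(default_templates()[1], layout,
                            np.random.default_rng(0), jitter=False)
    table = _frames_to_table(xy, {})
    key = CimarKey(mouse="probe", excursion=1, start_frame=0,
                   end_frame=len(xy) - 1)
    return Excursion(key=key, trajectory=table.frames, frame_rate=FPS)


# --- cohort designs ---------------------------------------------------------

GENOTYPES = ("wildtype", "Th het", "Ddc het", "ThDdc het")
CROSSES = ("maternal", "paternal")
SEXES = ("male", "female")


def _default_chains() -> dict:
    """Sex-specific 6-module transition chains (females more perseverative)."""
    k = 6
    male = np.full((k, k), 1.0)
    np.fill_diagonal(male, 2.0)
    male /= male.sum(axis=1, keepdims=True)
    female = np.full((k, k), 0.5)
    np.fill_diagonal(female, 4.0)
    female /= female.sum(axis=1, keepdims=True)
    return {"male": male, "female": female}


@dataclass
class CohortDesign:
    """Planted cohort: sample sizes, Poisson module rates, planted effects.

    ``rate_effects`` maps (genotype, cross) to a per-module rate multiplier
    vector applied on top of ``base_rates``; cells not listed use the base
    rates.  ``sex_effects`` maps a sex to a per-module multiplier (the
    default biases female module usage, so male and female chains differ in
    stationary distribution).  ``chains`` maps sex to a module transition
    matrix governing expression order.
    """

    n_per_cell: int = 25
    genotypes: tuple = GENOTYPES
    crosses: tuple = CROSSES
    sexes: tuple = SEXES
    phase: str = "foraging"
    base_rates: tuple = (4.0, 4.0, 4.0, 4.0, 4.0, 4.0)
    rate_effects: dict = field(default_factory=dict)
    sex_effects: dict = field(default_factory=lambda: {
        "female": (1.5, 1.25, 1.0, 0.8, 0.7, 0.6)})
    chains: dict = field(default_factory=_default_chains)

    def cell_rates(self, genotype: str, cross: str,
                   sex: str = "male") -> np.ndarray:
        lam = np.asarray(self.base_rates, dtype=float)
        mult = self.rate_effects.get((genotype, cross))
        if mult is not None:
            lam = lam * np.asarray(mult, dtype=float)
        sex_mult = self.sex_effects.get(sex)
        if sex_mult is not None:
            lam = lam * np.asarray(sex_mult, dtype=float)
        if np.any(lam < 0):
            raise ValueError("rates must be non-negative")
        return lam


def generate_module_counts(design: CohortDesign, seed=None):
    """Per-mouse Poisson module counts under the design's planted rates.

    Returns (counts DataFrame, metadata DataFrame, truth dict).
    """
    rng = np.random.default_rng(seed)
    k = len(design.base_rates)
    module_ids = list(range(1, k + 1))
    rows, meta = [], []
    truth = {"lambda": {}, "rate_effects": dict(design.rate_effects)}
    i = 0
    for sex in design.sexes:
        for cross in design.crosses:
            for genotype in design.genotypes:
                lam = design.cell_rates(genotype, cross, sex)
                truth["lambda"][(sex, cross, genotype)] = lam.copy()
                for _ in range(design.n_per_cell):
                    rows.append(rng.poisson(lam))
                    meta.append({"mouse": f"m{i:04d}", "sex": sex,
                                 "cross": cross, "genotype": genotype,
                                 "phase": design.phase})
                    i += 1
    counts = pd.DataFrame(rows, columns=module_ids,
                          index=[m["mouse"] for m in meta])
    metadata = pd.DataFrame(meta).set_index("mouse")
    return counts, metadata, truth


def generate_cohort(design: CohortDesign, templates=None,
                    layout: ArenaLayout | None = None, seed=None,
                    out_dir=None):
    """Full tracking-level cohort with planted modules, counts and chains.

    Per mouse, the number of expressed modules is Poisson per the design's
    rates and their order follows the sex's transition chain (restricted to
    the modules the mouse expresses).  Returns a dict with per-mouse
    sessions (or file paths when ``out_dir`` is given), the design table,
    per-excursion truth, and the planted-parameter record.
    """
    templates = templates or default_templates()
    layout = layout or build_default_arena()
    counts, metadata, truth = generate_module_counts(design, seed)
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed if seed is not None else 0)
    mouse_seeds = ss.spawn(len(metadata) + 1)[1:]
    sessions, truth_rows = {}, []
    for (mouse, md), mseed in zip(metadata.iterrows(), mouse_seeds):
        rng = np.random.default_rng(mseed)
        chain = np.asarray(design.chains[md["sex"]], dtype=float)
        tokens = _sequence_from_counts(counts.loc[mouse].to_numpy(), chain, rng)
        session, seq_truth = generate_session(
            templates, tokens, layout, seed=rng,
            metadata={"mouse": mouse, **md.to_dict()})
        for num, tid in enumerate(seq_truth, start=1):
            truth_rows.append({"mouse": mouse, "excursion": num,
                               "template": tid})
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            path = out_dir / f"{mouse}.csv"
            session.frames.to_csv(path, index=False)
            sessions[mouse] = str(path)
        else:
            sessions[mouse] = session
    truth["per_excursion"] = pd.DataFrame(truth_rows)
    if out_dir is not None:
        metadata.assign(file=[sessions[m] for m in metadata.index]) \
            .to_csv(Path(out_dir) / "design.csv")
    return {"sessions": sessions, "metadata": metadata, "counts": counts,
            "truth": truth}


def _sequence_from_counts(counts: np.ndarray, chain: np.ndarray,
                          rng: np.random.Generator) -> list:
    """Order a mouse's module multiset along its sex's transition chain."""
    remaining = counts.astype(int).copy()
    total = int(remaining.sum())
    if total == 0:
        return []
    seq = []
    probs = remaining / remaining.sum()
    current = int(rng.choice(len(remaining), p=probs))
    seq.append(current)
    remaining[current] -= 1
    while remaining.sum() > 0:
        w = chain[current] * (remaining > 0)
        if w.sum() == 0:
            w = (remaining > 0).astype(float)
        w = w / w.sum()
        current = int(rng.choice(len(remaining), p=w))
        seq.append(current)
        remaining[current] -= 1
    return [s + 1 for s in seq]  # template ids are 1-based


# --- allelic replicates -----------------------------------------------------

def generate_allelic_dataset(n_replicates: int = 18,
                             markers_per_category: int = 15,
                             rho: float = 0.8,
                             categories: tuple = ("Gaba", "Glut"),
                             bias_mean: float = 5.0, bias_sd: float = 2.0,
                             base_expression: float = 50.0,
                             seed=None):
    """Allelic replicates with a planted imprinting-marker coupling.

    The focal gene's imprinting signal (maternal - paternal) varies across
    replicates; markers of ``categories[0]`` correlate +rho with it, markers
    of ``categories[1]`` correlate -rho.  Returns (AllelicExpressionMatrix,
    MarkerSet, truth dict).
    """
    if n_replicates < 3:
        raise ValueError("need >= 3 replicates")
    rng = np.random.default_rng(seed)
    reps = [f"rep{i + 1}" for i in range(n_replicates)]
    z = rng.standard_normal(n_replicates)  # standardized bias
    signal = bias_mean + bias_sd * z
    maternal = np.clip(base_expression + signal / 2.0, 0.0, None)
    paternal = np.clip(base_expression - signal / 2.0, 0.0, None)
    cats = {}
    cols = {}
    for c, cat in enumerate(categories):
        sign = +1.0 if c == 0 else -1.0
        for j in range(markers_per_category):
            name = f"{cat.lower()}_marker{j + 1}"
            noise = rng.standard_normal(n_replicates)
            latent = sign * rho * z + np.sqrt(max(1 - rho**2, 0.0)) * noise
            cols[name] = 10.0 + 2.0 * latent
            cats[name] = cat
    matrix = AllelicExpressionMatrix(
        maternal=pd.Series(maternal, index=reps),
        paternal=pd.Series(paternal, index=reps),
        markers=pd.DataFrame(cols, index=reps),
        replicate_cross=pd.Series(
            ["initial"] * (n_replicates // 2)
            + ["reciprocal"] * (n_replicates - n_replicates // 2), index=reps),
    )
    truth = {"rho": rho, "bias_mean": bias_mean, "bias_sd": bias_sd,
             "positive_category": categories[0]}
    return matrix, MarkerSet(categories=cats), truth
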