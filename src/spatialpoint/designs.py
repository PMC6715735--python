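"""Construction of testing layouts and trial schedules.

The four bundled presets (``exp1`` … ``exp4``) share one canonical plan-view
arrangement: the four target boxes sit in a ±12.5° fan to the "North" of the
start zone (two visual lines, 25° apart, both passing through the start
zone, with the blue box nearer than the pink and the red nearer than the
yellow), while the pointing zones lie to the South, behind the central
obscuring wall.  Box distances vary from layout to layout; the 25° line
separation never does.

Published coordinates for individual layouts are not part of the package;
layouts are sampled from the constraint family instead (or loaded from file
via :mod:`spatialpoint.io`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import (
    PlanPoint,
    Scene,
    WallSegment,
    as_point,
    bearing_between,
    signed_error,
    wrap_angle,
)

__all__ = [
    "BOX_COLOURS",
    "ConstraintError",
    "ConfigurationError",
    "LayoutConstraints",
    "TrialDesign",
    "Experiment",
    "make_box_layout",
    "validate_layout",
    "enumerate_trials",
    "mirror_zones",
    "scale_scene",
    "make_experiment",
    "PRESETS",
]

BOX_COLOURS = ("blue", "pink", "red", "yellow")

#: Canonical observer-side geometry (metres).  Boxes are North, zones South.
_START = PlanPoint(0.0, -2.2)
_WALL_PIVOT = PlanPoint(0.0, -1.0)
_FACING = 90.0  # bearing faced while viewing the boxes from the start zone

_ZONES_EXP1 = {"A": PlanPoint(-2.0, -1.4), "B": PlanPoint(-0.9, -1.25), "C": PlanPoint(2.0, -1.8)}
_ZONES_EXP4 = {
    "B": PlanPoint(-1.0, -1.3),
    "C": PlanPoint(-2.2, -2.1),
    "D": PlanPoint(1.0, -1.3),
    "E": PlanPoint(2.2, -2.1),
}

#: Wall orientations available to the presets, as line orientations in degrees.
WALL_ORIENTATIONS = {"EW": 0.0, "NW": 135.0, "NE": 45.0}


class ConstraintError(ValueError):
    """Layout constraints are infeasible or violated."""


class ConfigurationError(ValueError):
    """An experiment/trial configuration is inconsistent."""


@dataclass(frozen=True)
class LayoutConstraints:
    """Constraint family from which box layouts are sampled.

    ``axis_bearing`` is the bisector of the two visual lines as seen from the
    start zone; the lines sit at ±``line_separation``/2 around it.  The near
    boxes (blue, red) are drawn from ``near_range`` and the far boxes (pink,
    yellow) from ``far_range`` (metres from the start zone), with the
    depth-ordering constraint blue < pink and red < yellow enforced.
    """

    line_separation: float = 25.0
    axis_bearing: float = _FACING
    near_range: tuple[float, float] = (1.8, 2.2)
    far_range: tuple[float, float] = (2.4, 2.8)
    min_depth_gap: float = 0.15

    def __post_init__(self):
        for lo, hi in (self.near_range, self.far_range):
            if not (0 < lo <= hi):
                raise ConstraintError(f"bad distance range ({lo}, {hi})")
        if self.far_range[1] < self.near_range[0] + self.min_depth_gap:
            raise ConstraintError("far range cannot satisfy the depth ordering")


def _wall_segment(orientation_label: str, pivot: PlanPoint = _WALL_PIVOT,
                  half_length: float = 2.6) -> WallSegment:
    ang = math.radians(WALL_ORIENTATIONS[orientation_label])
    d = np.array([math.cos(ang), math.sin(ang)])
    p = pivot.as_array()
    return WallSegment(PlanPoint(*(p - half_length * d)), PlanPoint(*(p + half_length * d)),
                       label=orientation_label)


def _sample_distance(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(rng.uniform(lo, hi))


def make_box_layout(constraints: LayoutConstraints, seed: int, *,
                    start_zone: PlanPoint = _START,
                    pointing_zones: dict | None = None,
                    wall: str = "EW",
                    bounds=((-3.0, 3.0), (-3.0, 3.0))) -> Scene:
    """Sample one box layout satisfying the constraint family.

    Deterministic for a fixed ``seed``.  Blue and pink go on the
    anticlockwise visual line, red and yellow on the clockwise one.
    """
    rng = np.random.default_rng(seed)
    half = constraints.line_separation / 2.0
    line_acw = constraints.axis_bearing + half   # blue, pink
    line_cw = constraints.axis_bearing - half    # red, yellow

    start = as_point(start_zone)

    def place(bearing_deg: float, dist: float) -> PlanPoint:
        th = math.radians(bearing_deg)
        return PlanPoint(start.x + dist * math.cos(th), start.y + dist * math.sin(th))

    boxes = {}
    for line, near_colour, far_colour in ((line_acw, "blue", "pink"), (line_cw, "red", "yellow")):
        d_near = _sample_distance(rng, *constraints.near_range)
        lo_far = max(constraints.far_range[0], d_near + constraints.min_depth_gap)
        if lo_far > constraints.far_range[1]:
            raise ConstraintError(
                f"no feasible far distance beyond {d_near:.2f} m within {constraints.far_range}"
            )
        d_far = _sample_distance(rng, lo_far, constraints.far_range[1])
        boxes[near_colour] = place(line, d_near)
        boxes[far_colour] = place(line, d_far)

    obscuring = _wall_segment(wall)
    scene = Scene(
        start_zone=start,
        pointing_zones=dict(pointing_zones if pointing_zones is not None else _ZONES_EXP1),
        boxes=boxes,
        walls=[obscuring],
        obscuring_wall=obscuring,
        bounds=bounds,
        metadata={"facing_bearing": constraints.axis_bearing, "layout_seed": int(seed)},
    )
    validate_layout(scene, constraints)
    return scene


def validate_layout(scene: Scene, constraints: LayoutConstraints, tol: float = 1e-6) -> None:
    """Re-check the layout criteria directly from the scene geometry.

    Independent of how the scene was produced: everything is recomputed from
    the stored coordinates.  Raises :class:`ConstraintError` on violation.
    """
    s = scene.start_zone
    b = {c: bearing_between(s, scene.box(c)) for c in BOX_COLOURS}
    d = {c: math.dist(s, scene.box(c)) for c in BOX_COLOURS}

    # (1) blue/pink share a visual line through the start zone; likewise red/yellow
    if abs(signed_error(b["blue"], b["pink"])) > tol:
        raise ConstraintError("blue and pink do not share a visual line through the start zone")
    if abs(signed_error(b["red"], b["yellow"])) > tol:
        raise ConstraintError("red and yellow do not share a visual line through the start zone")
    # (2) depth ordering
    if not (d["blue"] < d["pink"] and d["red"] < d["yellow"]):
        raise ConstraintError("depth ordering violated (blue<pink, red<yellow required)")
    # (3) the two lines subtend the required angle at the start zone
    sep = abs(signed_error(b["blue"], b["red"]))
    if abs(sep - constraints.line_separation) > tol:
        raise ConstraintError(
            f"visual lines are {sep:.6f}° apart, expected {constraints.line_separation}°"
        )
    # (4) all boxes inside the room
    (x0, x1), (y0, y1) = scene.bounds
    for c in BOX_COLOURS:
        p = scene.box(c)
        if not (x0 - tol <= p.x <= x1 + tol and y0 - tol <= p.y <= y1 + tol):
            raise ConstraintError(f"{c} box at {p} lies outside the room bounds")


def mirror_zones(scene: Scene, centre_x: float | None = None,
                 mapping={"A": "D", "B": "E", "C": "F"}) -> Scene:
    """Add mirror-image pointing zones reflected across a North–South centre line.

    Reflecting twice restores the original zone positions, and every mirrored
    zone keeps its distance to the centre line.
    """
    if centre_x is None:
        if "centre_line_x" in scene.metadata:
            centre_x = float(scene.metadata["centre_line_x"])
        else:
            centre_x = 0.5 * (scene.bounds[0][0] + scene.bounds[0][1])
    missing = [z for z in mapping if z not in scene.pointing_zones]
    if missing:
        raise ConfigurationError(f"cannot mirror: zones {missing} absent from scene")
    zones = dict(scene.pointing_zones)
    for src, dst in mapping.items():
        p = zones[src]
        zones[dst] = PlanPoint(2.0 * centre_x - p.x, p.y)
    return replace(scene, pointing_zones=zones)


def scale_scene(scene: Scene, factor: float) -> Scene:
    """Scale a scene in the x–y plane about the origin (room rescaling)."""
    if factor <= 0:
        raise ConfigurationError("scale factor must be positive")

    def sp(p: PlanPoint) -> PlanPoint:
        return PlanPoint(factor * p.x, factor * p.y)

    def sw(w: WallSegment) -> WallSegment:
        return WallSegment(sp(w.a), sp(w.b), w.label)

    (x0, x1), (y0, y1) = scene.bounds
    return Scene(
        start_zone=sp(scene.start_zone),
        pointing_zones={k: sp(v) for k, v in scene.pointing_zones.items()},
        boxes={k: sp(v) for k, v in scene.boxes.items()},
        walls=[sw(w) for w in scene.walls],
        obscuring_wall=sw(scene.obscuring_wall) if scene.obscuring_wall is not None else None,
        bounds=((factor * x0, factor * x1), (factor * y0, factor * y1)),
        metadata=dict(scene.metadata),
    )


@dataclass
class TrialDesign:
    """Enumerated (run × layout × condition × box × shot) schedule."""

    experiment_id: str
    rows: pd.DataFrame
    shots_per_box: int

    def __len__(self) -> int:
        return len(self.rows)


def enumerate_trials(experiment_id: str,
                     n_layouts: int,
                     zones_by_route: dict[str, tuple[str, ...]] | None = None,
                     shots_per_box: int = 8,
                     box_colours: tuple[str, ...] = BOX_COLOURS,
                     conditions: list[tuple[str, str]] | None = None,
                     n_runs: int = 1,
                     default_wall: str = "EW",
                     facings: tuple[str, ...] | None = None,
                     order_seed: int | None = None) -> TrialDesign:
    """Full-factorial trial schedule for one participant.

    Two styles of condition factor are supported: ``zones_by_route`` maps a
    route label (``direct``/``indirect``) to the pointing zones tested under
    it (all with the ``default_wall``), while ``conditions`` enumerates
    (zone, wall-orientation) pairs directly, as in the paired-wall design.
    The resulting row count is the closed-form product of the factors, summed
    over routes.
    """
    if n_layouts <= 0 or shots_per_box <= 0 or n_runs <= 0:
        raise ConfigurationError("all design counts must be positive")
    if (zones_by_route is None) == (conditions is None):
        raise ConfigurationError("give exactly one of zones_by_route or conditions")

    layout_ids = [f"L{i + 1}" for i in range(n_layouts)]
    cells: list[tuple[str, str, str]] = []  # (route, zone, wall)
    if zones_by_route is not None:
        for route, zones in zones_by_route.items():
            for z in zones:
                cells.append((route, z, default_wall))
    else:
        cells = [("direct", z, w) for z, w in conditions]

    facing_list = list(facings) if facings is not None else [None]
    recs = []
    for run in range(1, n_runs + 1):
        for layout in layout_ids:
            for route, zone, wall in cells:
                for facing in facing_list:
                    for colour in box_colours:
                        for shot in range(1, shots_per_box + 1):
                            recs.append((run, layout, wall, route, zone, facing, colour, shot))
    rows = pd.DataFrame(
        recs,
        columns=["run", "layout_id", "wall", "route", "zone_id", "facing", "box_colour", "shot_index"],
    )
    if facings is None:
        rows = rows.drop(columns="facing")
    if order_seed is not None:
        # pseudo-random presentation order: seeded shuffle within each
        # (run, layout, condition) block
        rng = np.random.default_rng(order_seed)
        group_keys = ["run", "layout_id", "wall", "route", "zone_id"]
        order = []
        for idxs in rows.groupby(group_keys, sort=False).indices.values():
            order.extend(rng.permutation(idxs))
        rows = rows.iloc[order].reset_index(drop=True)
    return TrialDesign(experiment_id=experiment_id, rows=rows, shots_per_box=shots_per_box)


@dataclass
class Experiment:
    """A bundle of scenes, routes, and the trial schedule for one experiment."""

    experiment_id: str
    scenes: dict[tuple[str, str], Scene]   # (layout_id, wall orientation) -> Scene
    design: TrialDesign
    routes: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def scene_for(self, layout_id: str, wall: str) -> Scene:
        try:
            return self.scenes[(layout_id, wall)]
        except KeyError:
            raise ConfigurationError(
                f"no scene for layout {layout_id!r} with wall {wall!r} in {self.experiment_id}"
            )

    def path_for(self, layout_id: str, wall: str, zone_id: str, route: str) -> np.ndarray:
        """Walking polyline from the start zone to a pointing zone.

        Falls back to the straight (direct) segment when no explicit route is
        configured, e.g. for designs where the walls appear only after the
        participant has left the start zone.
        """
        key = (zone_id, route)
        if key in self.routes:
            return self.routes[key]
        scene = self.scene_for(layout_id, wall)
        return np.array([scene.start_zone, scene.zone(zone_id)], dtype=float)

    def layout_ids(self) -> list[str]:
        return sorted({lid for lid, _ in self.scenes}, key=lambda s: int(s[1:]))


def _layout_seeds(master_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(s) & 0x7FFFFFFF for s in ss.generate_state(n)]


def _mirror_path(path: np.ndarray) -> np.ndarray:
    out = np.array(path, dtype=float)
    out[:, 0] *= -1.0
    return out


def _exp1_routes() -> dict[tuple[str, str], np.ndarray]:
    s = _START
    detour_south = (-0.4, -2.9)
    west = (-2.8, -2.9)
    east = (2.8, -2.9)
    routes = {
        ("A", "indirect"): np.array([s, detour_south, west, _ZONES_EXP1["A"]], dtype=float),
        ("B", "indirect"): np.array(
            [s, detour_south, west, (-2.8, -1.25), _ZONES_EXP1["B"]], dtype=float
        ),
        ("C", "indirect"): np.array(
            [s, detour_south, east, (2.8, -1.8), _ZONES_EXP1["C"]], dtype=float
        ),
    }
    for z, p in _ZONES_EXP1.items():
        routes[(z, "direct")] = np.array([s, p], dtype=float)
    return routes


def _build_scenes(n_layouts: int, seed: int, constraints: LayoutConstraints,
                  pointing_zones: dict, walls: tuple[str, ...],
                  extra_walls: list[WallSegment] | None = None) -> dict:
    scenes = {}
    for lid, s in zip([f"L{i + 1}" for i in range(n_layouts)], _layout_seeds(seed, n_layouts)):
        base = make_box_layout(constraints, s, pointing_zones=pointing_zones, wall=walls[0])
        for w in walls:
            sc = base if w == walls[0] else replace(base, obscuring_wall=_wall_segment(w),
                                                    walls=[_wall_segment(w)])
            if extra_walls:
                sc = replace(sc, walls=list(sc.walls) + list(extra_walls))
            scenes[(lid, w)] = sc
    return scenes


def exp1(n_layouts: int = 9, seed: int = 0,
         direct_zones: tuple[str, ...] = ("A", "C"),
         constraints: LayoutConstraints | None = None) -> Experiment:
    """Direct/indirect walking design: 8 shots per box, zones A–C.

    The 9-layout arm yields 1,440 pointing directions per participant, the
    4-layout arm 640.  ``direct_zones`` selects the two zones tested in the
    direct-walking condition.
    """
    constraints = constraints or LayoutConstraints()
    inner = WallSegment(PlanPoint(-0.4, -3.0), PlanPoint(-0.4, -1.6), label="inner-partition")
    scenes = _build_scenes(n_layouts, seed, constraints, _ZONES_EXP1, ("EW",), [inner])
    design = enumerate_trials(
        "exp1", n_layouts,
        zones_by_route={"indirect": ("A", "B", "C"), "direct": tuple(direct_zones)},
        shots_per_box=8,
    )
    return Experiment("exp1", scenes, design, _exp1_routes())


def exp2(n_layouts: int = 6, seed: int = 0,
         constraints: LayoutConstraints | None = None) -> Experiment:
    """Facing-direction design: zones A and C, three poster positions, 6 shots."""
    constraints = constraints or LayoutConstraints()
    scenes = _build_scenes(n_layouts, seed, constraints, _ZONES_EXP1, ("EW",))
    design = enumerate_trials(
        "exp2", n_layouts,
        zones_by_route={"indirect": ("A", "C")},
        shots_per_box=6,
        facings=("N", "S", "W"),
    )
    return Experiment("exp2", scenes, design, _exp1_routes())


def exp3(n_layouts: int = 4, seed: int = 0,
         constraints: LayoutConstraints | None = None) -> Experiment:
    """Mirrored-zone design in a room scaled by 1.5 in the x–y plane."""
    constraints = constraints or LayoutConstraints()
    scenes: dict[tuple[str, str], Scene] = {}
    for lid, s in zip([f"L{i + 1}" for i in range(n_layouts)], _layout_seeds(seed, n_layouts)):
        base = make_box_layout(constraints, s, pointing_zones=_ZONES_EXP1, wall="EW")
        sc = scale_scene(base, 1.5)
        sc.metadata["centre_line_x"] = 0.0
        scenes[(lid, "EW")] = mirror_zones(sc, centre_x=0.0)
    routes: dict[tuple[str, str], np.ndarray] = {}
    for (z, r), path in _exp1_routes().items():
        scaled = 1.5 * np.asarray(path, dtype=float)
        routes[(z, r)] = scaled
        routes[({"A": "D", "B": "E", "C": "F"}[z], r)] = _mirror_path(scaled)
    design = enumerate_trials(
        "exp3", n_layouts,
        zones_by_route={"indirect": ("A", "B", "C", "D", "E", "F")},
        shots_per_box=6,
    )
    return Experiment("exp3", scenes, design, routes)


#: Which wall orientations each exp-4 pointing zone is paired with.  Western
#: zones see the East-West and the North-West slanted wall; eastern zones the
#: East-West and the North-East slanted wall.
EXP4_CONDITIONS: list[tuple[str, str]] = [
    ("B", "EW"), ("B", "NW"),
    ("C", "EW"), ("C", "NW"),
    ("D", "EW"), ("D", "NE"),
    ("E", "EW"), ("E", "NE"),
]


def exp4(n_layouts: int = 4, seed: int = 0,
         constraints: LayoutConstraints | None = None) -> Experiment:
    """Paired wall-orientation design: 8 conditions × 4 layouts × 2 runs.

    Walls appear only after the participant leaves the start zone, so the
    walking routes are direct; paired conditions differ in nothing but the
    orientation of the obscuring wall.
    """
    constraints = constraints or LayoutConstraints()
    scenes = _build_scenes(n_layouts, seed, constraints, _ZONES_EXP4, ("EW", "NW", "NE"))
    design = enumerate_trials(
        "exp4", n_layouts,
        conditions=EXP4_CONDITIONS,
        shots_per_box=6,
        n_runs=2,
    )
    return Experiment("exp4", scenes, design)


def sample_projection_scene(rng: np.random.Generator,
                            plane_offset: float = 1.77) -> tuple[Scene, str, str]:
    """One randomised wall/target/zone configuration in general position.

    Used for property checks of the projection-plane rule.  The scene keeps
    the structural features of the testing rooms: the start zone and the
    pointing zone lie behind the obscuring wall, with the pointing zone
    between the start zone's depth and the wall (in the rooms the zones were
    always nearer the wall than the start zone); the target is on the far
    side between the wall and the projection plane (targets sat within the
    fitted plane offset of the wall); and the zone is displaced laterally
    clear of the target's sight-line fan.  Orientation and position of the
    whole arrangement are random.

    Returns (scene, zone_id, box_colour) with a single target box.
    """
    psi = rng.uniform(0.0, 360.0)          # wall orientation
    th = math.radians(psi)
    d = np.array([math.cos(th), math.sin(th)])      # along the wall
    n = np.array([-d[1], d[0]])                     # unit normal, target side
    pivot = rng.uniform(-5.0, 5.0, size=2)          # world position of the wall

    def world(u, v):
        return PlanPoint(*(pivot + u * n + v * d))

    u_start = -rng.uniform(1.0, 2.5)
    v_start = rng.uniform(-1.0, 1.0)
    u_box = rng.uniform(0.15, plane_offset - 0.15)
    v_box = rng.uniform(-1.2, 1.2)
    # lateral position of the projected target (for zone clearance)
    t = (plane_offset - u_start) / (u_box - u_start)
    v_proj = v_start + t * (v_box - v_start)
    side = rng.choice([-1.0, 1.0])
    v_zone = side * (max(abs(v_proj), abs(v_box), abs(v_start)) + rng.uniform(0.4, 2.0))
    u_zone = rng.uniform(u_start + 0.1, -0.2)

    wall = WallSegment(world(0.0, -4.0), world(0.0, 4.0), label="sampled")
    return (
        Scene(
            start_zone=world(u_start, v_start),
            pointing_zones={"Z": world(u_zone, v_zone)},
            boxes={"blue": world(u_box, v_box)},
            walls=[wall],
            obscuring_wall=wall,
            bounds=((pivot[0] - 8, pivot[0] + 8), (pivot[1] - 8, pivot[1] + 8)),
            metadata={"facing_bearing": wrap_angle(math.degrees(math.atan2(n[1], n[0])))},
        ),
        "Z",
        "blue",
    )


PRESETS = {"exp1": exp1, "exp2": exp2, "exp3": exp3, "exp4": exp4}


def make_experiment(preset: str, **kwargs) -> Experiment:
    """Build a bundled experiment preset (``exp1`` … ``exp4``)."""
    try:
        builder = PRESETS[preset]
    except KeyError:
        raise ConfigurationError(f"unknown preset {preset!r}; have {sorted(PRESETS)}")
    return builder(**kwargs)
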