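"""Plan-view (2-D) geometry primitives.

Everything downstream — scene construction, the candidate pointing models,
and the error statistics — works in a flat plan view measured in metres.
Directions are *bearings* in degrees, measured anticlockwise from due East
(so the nominal "North" of a scene map is +90°) and wrapped into the
half-open interval (−180, 180].  A positive signed pointing error means the
shot was anticlockwise of the true target direction in plan view.

Wall height and observer eye height never enter the analysis; walls are
carried as 2-D segments whose *infinite line* is what the projection-plane
model consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "COINCIDENT_TOL",
    "GeometryError",
    "DegenerateGeometryError",
    "ParallelLinesError",
    "BehindOriginError",
    "PlanPoint",
    "WallSegment",
    "Scene",
    "wrap_angle",
    "bearing_between",
    "signed_error",
    "wall_normal_toward",
    "ray_line_intersection",
    "offset_parallel_line",
    "transform_scene",
]

#: Points closer than this (metres) are treated as coincident.
COINCIDENT_TOL = 1e-9


class GeometryError(ValueError):
    """Base class for degenerate plan-view geometry."""


class DegenerateGeometryError(GeometryError):
    """Coincident points, zero-length walls, collinear side points."""


class ParallelLinesError(GeometryError):
    """A ray was parallel to the line it was intersected with."""


class BehindOriginError(GeometryError):
    """The ray–line intersection lies behind the ray origin."""


class PlanPoint(NamedTuple):
    """A position in the plan view: x metres East, y metres North."""

    x: float
    y: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


def as_point(p) -> PlanPoint:
    """Coerce a 2-sequence to a :class:`PlanPoint` with finite coordinates."""
    x, y = float(p[0]), float(p[1])
    if not (math.isfinite(x) and math.isfinite(y)):
        raise DegenerateGeometryError(f"non-finite plan point {p!r}")
    return PlanPoint(x, y)


def wrap_angle(deg):
    """Wrap an angle (degrees) into (−180, 180].

    Works on scalars and arrays; scalars come back as ``float``.
    Idempotent: ``wrap_angle(wrap_angle(x)) == wrap_angle(x)``.
    """
    r = np.remainder(deg, 360.0)
    r = np.where(r > 180.0, r - 360.0, r)
    if np.ndim(deg) == 0:
        return float(r)
    return r


def bearing_between(origin, target) -> float:
    """Bearing of the vector origin→target, degrees anticlockwise from East."""
    o = as_point(origin)
    t = as_point(target)
    dx, dy = t.x - o.x, t.y - o.y
    if math.hypot(dx, dy) < COINCIDENT_TOL:
        raise DegenerateGeometryError(
            f"cannot take a bearing between coincident points {o} and {t}"
        )
    return wrap_angle(math.degrees(math.atan2(dy, dx)))


def signed_error(shot_deg, true_deg):
    """Signed pointing error: wrapped ``shot − true``, anticlockwise positive."""
    return wrap_angle(np.asarray(shot_deg, dtype=float) - np.asarray(true_deg, dtype=float))


@dataclass(frozen=True)
class WallSegment:
    """A wall (partition) in plan view, stored by its two endpoints.

    Only the position and orientation of the segment's infinite line matter
    to the models; ``label`` is free text such as ``"East-West"``.
    """

    a: PlanPoint
    b: PlanPoint
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "a", as_point(self.a))
        object.__setattr__(self, "b", as_point(self.b))
        if math.hypot(self.b.x - self.a.x, self.b.y - self.a.y) < COINCIDENT_TOL:
            raise DegenerateGeometryError("wall endpoints coincide")

    @property
    def direction(self) -> np.ndarray:
        """Unit vector along the wall from ``a`` to ``b``."""
        d = self.b.as_array() - self.a.as_array()
        return d / np.linalg.norm(d)

    @property
    def orientation(self) -> float:
        """Orientation of the wall line in [0, 180) degrees (modulo 180)."""
        ang = math.degrees(math.atan2(*self.direction[::-1]))
        return ang % 180.0

    def signed_offset(self, point) -> float:
        """Perpendicular signed distance of ``point`` from the wall line.

        The sign follows the left-hand normal of the a→b direction.
        """
        p = as_point(point).as_array() - self.a.as_array()
        d = self.direction
        return float(d[0] * p[1] - d[1] * p[0])


def wall_normal_toward(wall: WallSegment, side_point) -> float:
    """Bearing of the wall-line normal, signed to point toward ``side_point``."""
    off = wall.signed_offset(side_point)
    if abs(off) < COINCIDENT_TOL:
        raise DegenerateGeometryError(
            "side point lies on the wall line; normal direction is ambiguous"
        )
    d = wall.direction
    n = np.array([-d[1], d[0]]) if off > 0 else np.array([d[1], -d[0]])
    return wrap_angle(math.degrees(math.atan2(n[1], n[0])))


def ray_line_intersection(origin, direction_deg: float, line: WallSegment) -> PlanPoint:
    """Intersect the forward ray from ``origin`` with the infinite wall line.

    Raises :class:`ParallelLinesError` when the ray is parallel to the line
    and :class:`BehindOriginError` when the intersection is at a negative ray
    parameter.
    """
    o = as_point(origin).as_array()
    theta = math.radians(direction_deg)
    u = np.array([math.cos(theta), math.sin(theta)])
    a = line.a.as_array()
    v = line.direction
    # o + t*u = a + s*v  ->  [u, -v] [t, s]^T = a - o
    denom = u[0] * (-v[1]) - u[1] * (-v[0])
    if abs(denom) < 1e-12:
        raise ParallelLinesError("ray is parallel to the wall line")
    rhs = a - o
    t = (rhs[0] * (-v[1]) - rhs[1] * (-v[0])) / denom
    if t < -COINCIDENT_TOL:
        raise BehindOriginError("intersection lies behind the ray origin")
    return PlanPoint(o[0] + t * u[0], o[1] + t * u[1])


def offset_parallel_line(wall: WallSegment, distance: float, toward) -> WallSegment:
    """A line parallel to ``wall``, shifted ``distance`` metres toward a point.

    This is how the projection plane is built: parallel to the obscuring
    wall, offset on the target side.
    """
    if distance <= 0:
        raise ValueError("offset distance must be positive")
    n_bear = math.radians(wall_normal_toward(wall, toward))
    shift = distance * np.array([math.cos(n_bear), math.sin(n_bear)])
    return WallSegment(
        PlanPoint(*(wall.a.as_array() + shift)),
        PlanPoint(*(wall.b.as_array() + shift)),
        label=wall.label,
    )


@dataclass
class Scene:
    """One plan-view testing layout.

    Holds the viewing location (``start_zone``), the labelled pointing zones,
    the four coloured target boxes, the walls, and a reference to the single
    wall treated as the central obscuring wall for this condition.
    """

    start_zone: PlanPoint
    pointing_zones: dict[str, PlanPoint]
    boxes: dict[str, PlanPoint]
    walls: list[WallSegment] = field(default_factory=list)
    obscuring_wall: WallSegment | None = None
    bounds: tuple[tuple[float, float], tuple[float, float]] = ((-3.0, 3.0), (-3.0, 3.0))
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.start_zone = as_point(self.start_zone)
        self.pointing_zones = {k: as_point(v) for k, v in self.pointing_zones.items()}
        self.boxes = {k: as_point(v) for k, v in self.boxes.items()}

    def zone(self, zone_id: str) -> PlanPoint:
        try:
            return self.pointing_zones[zone_id]
        except KeyError:
            raise KeyError(f"unknown pointing zone {zone_id!r}; have {sorted(self.pointing_zones)}")

    def box(self, colour: str) -> PlanPoint:
        try:
            return self.boxes[colour]
        except KeyError:
            raise KeyError(f"unknown box {colour!r}; have {sorted(self.boxes)}")

    def true_direction(self, zone_id: str, colour: str) -> float:
        """Bearing from a pointing zone to a target box."""
        return bearing_between(self.zone(zone_id), self.box(colour))

    def box_centroid(self) -> PlanPoint:
        arr = np.mean([p.as_array() for p in self.boxes.values()], axis=0)
        return PlanPoint(*arr)


def _transform_point(p: PlanPoint, rot: np.ndarray, offset: np.ndarray) -> PlanPoint:
    return PlanPoint(*(rot @ p.as_array() + offset))


def transform_scene(scene: Scene, angle_deg: float = 0.0, offset=(0.0, 0.0)) -> Scene:
    """Rigidly rotate (about the origin) then translate a whole scene.

    Used mainly to check that model predictions are equivariant under rigid
    motions of the world.
    """
    th = math.radians(angle_deg)
    rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    off = np.asarray(offset, dtype=float)

    def tw(w: WallSegment) -> WallSegment:
        return WallSegment(_transform_point(w.a, rot, off), _transform_point(w.b, rot, off), w.label)

    corners = [
        rot @ np.array([x, y]) + off
        for x in scene.bounds[0]
        for y in scene.bounds[1]
    ]
    xs = [c[0] for c in corners]
    ys = [c[1] for c in corners]
    meta = dict(scene.metadata)
    if "facing_bearing" in meta:
        meta["facing_bearing"] = wrap_angle(meta["facing_bearing"] + angle_deg)
    return Scene(
        start_zone=_transform_point(scene.start_zone, rot, off),
        pointing_zones={k: _transform_point(v, rot, off) for k, v in scene.pointing_zones.items()},
        boxes={k: _transform_point(v, rot, off) for k, v in scene.boxes.items()},
        walls=[tw(w) for w in scene.walls],
        obscuring_wall=tw(scene.obscuring_wall) if scene.obscuring_wall is not None else None,
        bounds=((min(xs), max(xs)), (min(ys), max(ys))),
        metadata=meta,
    )
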