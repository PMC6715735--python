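"""The five candidate models of pointing direction.

Each model maps (scene, pointing zone, target box) to a predicted pointing
bearing; the predicted signed error is the wrapped difference from the true
target bearing.  In their veridical limits (unit gains, no compression,
target on the projection plane, unit mixture weight, noiseless consistent
retrofit input) all five reduce to the true direction.

* ``path_integration`` — the scene is remembered correctly but the walked
  path is misintegrated: every turn is scaled by a rotation gain and every
  step by a translation gain, so both the believed position and the believed
  heading drift along the route.
* ``abathic`` — the scene is encoded with a radial distortion about the
  start zone: distances are judged correctly at the abathic distance ``a``
  and compressed toward it elsewhere, d′ = a + c·(d − a).
* ``retrofit`` — inverse inference: one remembered location per (layout,
  box) is chosen to maximise the likelihood of all shots from every zone and
  wall condition jointly (a deliberately over-parameterised reference point,
  2 coordinates per retrofitted box).
* ``projection_plane`` — a zero-parameter rule: remembered targets all lie
  on a plane parallel to, and a fixed 1.77 m behind, the central obscuring
  wall, placed along the sight-line from the start zone.
* ``category_mixture`` — the response is a resultant-vector circular mean of
  the target's true direction from the actual zone (weight w) and its
  direction from an alternative pointing zone (weight 1 − w).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from scipy import optimize

from .geometry import (
    COINCIDENT_TOL,
    BehindOriginError,
    DegenerateGeometryError,
    GeometryError,
    ParallelLinesError,
    PlanPoint,
    Scene,
    bearing_between,
    offset_parallel_line,
    ray_line_intersection,
    signed_error,
    wall_normal_toward,
    wrap_angle,
)
from .noise import NoiseSpec

__all__ = [
    "MODEL_IDS",
    "PathIntegrationParams",
    "AbathicParams",
    "ProjectionPlaneParams",
    "MixtureParams",
    "RetrofitParams",
    "RetrofitResult",
    "IdentifiabilityError",
    "predict_path_integration",
    "predict_abathic",
    "predict_projection_plane",
    "predict_category_mixture",
    "retrofit_targets",
    "default_alternative_zone",
    "draw_remembered_locations",
    "coerce_params",
    "predict_direction",
    "predict_table",
]

MODEL_IDS = ("path_integration", "abathic", "retrofit", "projection_plane", "category_mixture")


class IdentifiabilityError(ValueError):
    """Retrofit input does not pin down a target location (e.g. single zone)."""


@dataclass(frozen=True)
class PathIntegrationParams:
    """Systematic per-step gains; unit gains reproduce veridical updating."""

    translation_gain: float = 1.0
    rotation_gain: float = 1.0
    step_length: float = 0.25  # metres; only matters for the stochastic variant

    def __post_init__(self):
        if self.translation_gain <= 0 or self.rotation_gain <= 0 or self.step_length <= 0:
            raise ValueError("gains and step length must be positive")


@dataclass(frozen=True)
class AbathicParams:
    abathic_distance: float = 3.0   # metres at which distance is judged correctly
    compression: float = 0.6        # in (0, 1]; 1 = no compression

    def __post_init__(self):
        if self.abathic_distance <= 0:
            raise ValueError("abathic distance must be positive")
        if not (0.0 < self.compression <= 1.0):
            raise ValueError("compression must lie in (0, 1]")


@dataclass(frozen=True)
class ProjectionPlaneParams:
    plane_offset: float = 1.77      # metres behind the obscuring wall, target side
    mode: str = "sightline"         # "sightline" (default) or "orthogonal" variant

    def __post_init__(self):
        if self.plane_offset <= 0:
            raise ValueError("plane offset must be positive")
        if self.mode not in ("sightline", "orthogonal"):
            raise ValueError("mode must be 'sightline' or 'orthogonal'")


@dataclass(frozen=True)
class MixtureParams:
    w_actual: float = 0.82          # weight of the actual zone's true direction
    alternative_zone: str | None = None  # None -> opposite-side rule

    def __post_init__(self):
        if not (0.0 <= self.w_actual <= 1.0):
            raise ValueError("w_actual must lie in [0, 1]")


@dataclass(frozen=True)
class RetrofitParams:
    """Remembered target locations, one per (layout, box)."""

    locations: dict = field(default_factory=dict)  # (layout_id, box_colour) -> PlanPoint


PARAM_TYPES = {
    "path_integration": PathIntegrationParams,
    "abathic": AbathicParams,
    "projection_plane": ProjectionPlaneParams,
    "category_mixture": MixtureParams,
    "retrofit": RetrofitParams,
}


def coerce_params(model_id: str, params=None):
    """Accept a params dataclass, a mapping, or None (defaults)."""
    if model_id not in PARAM_TYPES:
        raise ValueError(f"unknown model {model_id!r}; have {MODEL_IDS}")
    cls = PARAM_TYPES[model_id]
    if params is None:
        return cls()
    if isinstance(params, cls):
        return params
    if isinstance(params, dict):
        return cls(**params)
    raise TypeError(f"cannot interpret {type(params).__name__} as {cls.__name__}")


# ---------------------------------------------------------------------------
# noisy path integration


def _polyline_steps(path: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    seg = np.diff(np.asarray(path, dtype=float), axis=0)
    lengths = np.hypot(seg[:, 0], seg[:, 1])
    keep = lengths > COINCIDENT_TOL
    headings = np.degrees(np.arctan2(seg[keep, 1], seg[keep, 0]))
    return headings, lengths[keep]


def predict_path_integration(scene: Scene, path, zone_id: str, box: str,
                             params: PathIntegrationParams | None = None) -> float:
    """Pointing bearing under misintegrated self-motion along ``path``.

    The believed pose is rolled forward turn-by-turn and step-by-step with
    the gains applied; the intended bearing toward the (correctly
    remembered) target is then executed with the residual heading error
    ``actual − believed`` added back, because the pointer is oriented
    relative to the body.
    """
    params = coerce_params("path_integration", params)
    path = np.asarray(path, dtype=float)
    if path.ndim != 2 or len(path) < 2:
        raise GeometryError("walked path needs at least two vertices")
    if not np.allclose(path[0], scene.start_zone.as_array(), atol=1e-6):
        raise GeometryError("path must start at the start zone")
    if not np.allclose(path[-1], scene.zone(zone_id).as_array(), atol=1e-6):
        raise GeometryError(f"path must end at pointing zone {zone_id!r}")

    headings, lengths = _polyline_steps(path)
    h0 = float(scene.metadata.get("facing_bearing", headings[0]))
    believed, heading_err = _integrate_path(path[0], headings, lengths, h0,
                                            params.translation_gain, params.rotation_gain)
    intended = bearing_between(believed, scene.box(box))
    return wrap_angle(intended + heading_err)


# ---------------------------------------------------------------------------
# abathic-distance distortion


def remembered_box_abathic(scene: Scene, box: str, params: AbathicParams) -> PlanPoint:
    """Where the box is remembered under the radial compression about the start zone."""
    start = scene.start_zone.as_array()
    b = scene.box(box).as_array()
    d = float(np.linalg.norm(b - start))
    if d < COINCIDENT_TOL:
        raise DegenerateGeometryError("box coincides with the start zone")
    d_prime = params.compression * d + (1.0 - params.compression) * params.abathic_distance
    # written as box + (ratio-1)*(box-start) so that compression == 1 is an
    # exact fixed point in floating point
    out = b + (d_prime / d - 1.0) * (b - start)
    return PlanPoint(*out)


def predict_abathic(scene: Scene, zone_id: str, box: str,
                    params: AbathicParams | None = None) -> float:
    params = coerce_params("abathic", params)
    return bearing_between(scene.zone(zone_id), remembered_box_abathic(scene, box, params))


# ---------------------------------------------------------------------------
# projection plane


def projected_box(scene: Scene, box: str, params: ProjectionPlaneParams) -> PlanPoint:
    """Intersection of the start-zone sight-line with the projection plane.

    The plane is parallel to the central obscuring wall, offset
    ``plane_offset`` metres on the target side.  The ``orthogonal`` variant
    drops the target perpendicularly onto the plane instead.
    """
    if scene.obscuring_wall is None:
        raise GeometryError("scene has no designated obscuring wall")
    b = scene.box(box)
    plane = offset_parallel_line(scene.obscuring_wall, params.plane_offset, toward=b)
    off = plane.signed_offset(b)
    if abs(off) < COINCIDENT_TOL:
        return b  # the plane's fixed point: a target already on the plane
    if params.mode == "orthogonal":
        d = plane.direction
        n = np.array([-d[1], d[0]])
        return PlanPoint(*(b.as_array() - off * n))
    return ray_line_intersection(scene.start_zone, bearing_between(scene.start_zone, b), plane)


def predict_projection_plane(scene: Scene, zone_id: str, box: str,
                             params: ProjectionPlaneParams | None = None) -> float:
    params = coerce_params("projection_plane", params)
    return bearing_between(scene.zone(zone_id), projected_box(scene, box, params))


# ---------------------------------------------------------------------------
# category mixture


def default_alternative_zone(scene: Scene, zone_id: str) -> str:
    """Opposite-side rule for the alternative zone of the mixture model.

    Zones are ranked by their signed lateral offset from the sight axis
    (start zone along the facing bearing); the alternative is the laterally
    nearest zone on the other side of that axis, falling back to the
    laterally most distant other zone when no opposite-side zone exists.
    """
    facing = math.radians(float(scene.metadata.get("facing_bearing", 90.0)))
    u = np.array([math.cos(facing), math.sin(facing)])
    s = scene.start_zone.as_array()

    def lateral(p: PlanPoint) -> float:
        d = p.as_array() - s
        return float(u[0] * d[1] - u[1] * d[0])

    v0 = lateral(scene.zone(zone_id))
    others = {z: lateral(p) for z, p in scene.pointing_zones.items() if z != zone_id}
    if not others:
        raise DegenerateGeometryError("no alternative pointing zone in scene")
    opposite = {z: v for z, v in others.items() if v * v0 < 0}
    if opposite:
        return min(sorted(opposite), key=lambda z: abs(opposite[z]))
    return max(sorted(others), key=lambda z: abs(others[z] - v0))


def predict_category_mixture(scene: Scene, zone_id: str, box: str,
                             params: MixtureParams | None = None) -> float:
    params = coerce_params("category_mixture", params)
    actual_dir = scene.true_direction(zone_id, box)
    if params.w_actual >= 1.0:
        return actual_dir
    alt = params.alternative_zone or default_alternative_zone(scene, zone_id)
    alt_dir = scene.true_direction(alt, box)
    if params.w_actual <= 0.0:
        return alt_dir
    w = params.w_actual
    a1, a2 = math.radians(actual_dir), math.radians(alt_dir)
    x = w * math.cos(a1) + (1.0 - w) * math.cos(a2)
    y = w * math.sin(a1) + (1.0 - w) * math.sin(a2)
    if math.hypot(x, y) < COINCIDENT_TOL:
        raise DegenerateGeometryError(
            "mixture of antipodal directions with equal weights has no mean direction"
        )
    return wrap_angle(math.degrees(math.atan2(y, x)))


# ---------------------------------------------------------------------------
# retrofit (maximum-likelihood remembered locations)


@dataclass
class RetrofitResult:
    """ML remembered locations and the likelihood surfaces they came from."""

    ml_locations: dict                 # (layout_id, box_colour) -> PlanPoint
    surfaces: dict                     # same key -> (xs, ys, lnL) arrays
    grid_argmax: dict                  # same key -> PlanPoint before refinement
    n_parameters: int
    log_likelihood: float

    def location(self, layout_id: str, box: str) -> PlanPoint:
        return self.ml_locations[(layout_id, box)]


def _grid_axes(extent, resolution):
    (x0, x1), (y0, y1) = extent
    xs = np.arange(x0, x1 + 0.5 * resolution, resolution)
    ys = np.arange(y0, y1 + 0.5 * resolution, resolution)
    return xs, ys


def _shot_loglik(cand_xy: np.ndarray, zone_xy: np.ndarray, shots: np.ndarray,
                 noise: NoiseSpec) -> np.ndarray:
    """Summed shot log-likelihood for candidate locations (vectorised).

    ``cand_xy``: (G, 2) candidates; ``zone_xy``: (n, 2) zone of each shot;
    ``shots``: (n,) measured bearings in degrees.
    """
    total = np.zeros(len(cand_xy))
    # group by zone so each bearing field is computed once
    uniq, inv = np.unique(zone_xy, axis=0, return_inverse=True)
    for j, z in enumerate(uniq):
        sel = inv == j
        d = cand_xy - z[None, :]
        bear = np.degrees(np.arctan2(d[:, 1], d[:, 0]))
        dev = wrap_angle(shots[None, sel] - bear[:, None])
        total += noise.logpdf(dev).sum(axis=1)
    return total


def retrofit_targets(records: pd.DataFrame, experiment, noise: NoiseSpec | None = None,
                     grid_resolution: float = 0.1, extent=None, margin: float = 1.0,
                     refine: bool = True, store_surfaces: bool = True) -> RetrofitResult:
    """Fit one remembered location per (layout, box) to all shots jointly.

    The same location must explain every pointing zone and wall condition of
    the experiment; shots enter through the angular deviation between the
    measured bearing and the bearing from the shot's zone to the candidate
    location.  A coarse grid scan (ties broken toward the grid centroid)
    seeds a local simplex refinement.
    """
    noise = noise or NoiseSpec()
    if records is None or len(records) == 0:
        raise ValueError("retrofit needs a non-empty record table")
    first_scene = next(iter(experiment.scenes.values()))
    if extent is None:
        (x0, x1), (y0, y1) = first_scene.bounds
        extent = ((x0 - margin, x1 + margin), (y0 - margin, y1 + margin))
    xs, ys = _grid_axes(extent, grid_resolution)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    centroid = np.array([xs.mean(), ys.mean()])

    ml: dict = {}
    surfaces: dict = {}
    raw_argmax: dict = {}
    total_lnl = 0.0
    for (layout, box), grp in records.groupby(["layout_id", "box_colour"], sort=True):
        walls = grp["wall"].unique() if "wall" in grp else ["EW"]
        scene = experiment.scene_for(layout, walls[0])
        zone_xy = np.array([scene.zone(z) for z in grp["zone_id"]], dtype=float)
        if len(np.unique(zone_xy, axis=0)) < 2:
            raise IdentifiabilityError(
                f"layout {layout!r} box {box!r}: need shots from >= 2 distinct zones"
            )
        shots = grp["shot_direction_deg"].to_numpy(dtype=float)
        lnl = _shot_loglik(grid, zone_xy, shots, noise)
        best = lnl.max()
        tied = np.flatnonzero(lnl >= best - 1e-12)
        if len(tied) > 1:  # deterministic: prefer the candidate nearest the grid centroid
            dist = np.linalg.norm(grid[tied] - centroid, axis=1)
            tied = tied[np.lexsort((tied, dist))]
        idx = int(tied[0])
        peak = grid[idx]
        raw_argmax[(layout, box)] = PlanPoint(*peak)
        if refine:
            res = optimize.minimize(
                lambda p: -_shot_loglik(p[None, :], zone_xy, shots, noise)[0],
                x0=peak,
                method="Nelder-Mead",
                bounds=[extent[0], extent[1]],
                options={"xatol": 1e-4, "fatol": 1e-8},
            )
            peak = res.x
        ml[(layout, box)] = PlanPoint(*peak)
        total_lnl += float(_shot_loglik(np.asarray(peak)[None, :], zone_xy, shots, noise)[0])
        if store_surfaces:
            surfaces[(layout, box)] = (xs, ys, lnl.reshape(len(xs), len(ys)))

    return RetrofitResult(
        ml_locations=ml,
        surfaces=surfaces,
        grid_argmax=raw_argmax,
        n_parameters=2 * len(ml),
        log_likelihood=total_lnl,
    )


def draw_remembered_locations(experiment, displacement_sd: float,
                              rng: np.random.Generator) -> dict:
    """Random remembered-location set: true boxes plus isotropic displacement.

    Used when the retrofit model acts as a *generator* of synthetic data;
    displacements are clipped to the room bounds.
    """
    locations = {}
    for layout in experiment.layout_ids():
        wall = next(w for (lid, w) in experiment.scenes if lid == layout)
        scene = experiment.scene_for(layout, wall)
        (x0, x1), (y0, y1) = scene.bounds
        for colour, p in scene.boxes.items():
            xy = p.as_array() + rng.normal(0.0, displacement_sd, size=2)
            locations[(layout, colour)] = PlanPoint(
                float(np.clip(xy[0], x0, x1)), float(np.clip(xy[1], y0, y1))
            )
    return locations


# ---------------------------------------------------------------------------
# dispatch


def predict_direction(experiment, model_id: str, params, layout_id: str, wall: str,
                      route: str, zone_id: str, box: str) -> float:
    """Predicted pointing bearing for one design cell."""
    scene = experiment.scene_for(layout_id, wall)
    params = coerce_params(model_id, params)
    if model_id == "path_integration":
        path = experiment.path_for(layout_id, wall, zone_id, route)
        return predict_path_integration(scene, path, zone_id, box, params)
    if model_id == "abathic":
        return predict_abathic(scene, zone_id, box, params)
    if model_id == "projection_plane":
        return predict_projection_plane(scene, zone_id, box, params)
    if model_id == "category_mixture":
        return predict_category_mixture(scene, zone_id, box, params)
    if model_id == "retrofit":
        loc = params.locations.get((layout_id, box))
        if loc is None:
            raise ValueError(f"no remembered location for ({layout_id!r}, {box!r})")
        return bearing_between(scene.zone(zone_id), loc)
    raise ValueError(f"unknown model {model_id!r}")


CELL_KEYS = ["layout_id", "wall", "route", "zone_id", "box_colour"]


def _bearings(from_xy: np.ndarray, to_xy: np.ndarray) -> np.ndarray:
    d = np.asarray(to_xy, dtype=float) - np.asarray(from_xy, dtype=float)
    return wrap_angle(np.degrees(np.arctan2(d[:, 1], d[:, 0])))


class CellPredictor:
    """Vectorised predictions over the unique design cells of an experiment.

    Precomputes all static geometry (zone/box coordinates, wall normals,
    walking-path step decompositions, alternative-zone assignments) once, so
    that repeated prediction calls during model fitting are cheap.  The
    scalar ``predict_*`` functions above are the reference implementations;
    this class must agree with them cell by cell.
    """

    def __init__(self, experiment, cells: pd.DataFrame | None = None):
        if cells is None:
            cells = experiment.design.rows[CELL_KEYS].drop_duplicates().reset_index(drop=True)
        self.experiment = experiment
        self.cells = cells.reset_index(drop=True)
        n = len(self.cells)

        self.zone_xy = np.empty((n, 2))
        self.box_xy = np.empty((n, 2))
        self.start_xy = np.empty((n, 2))
        self.wall_anchor = np.empty((n, 2))   # a point on the obscuring wall line
        self.wall_normal = np.empty((n, 2))   # unit normal toward the target box
        self.alt_dir = np.empty(n)            # mixture: bearing from the alternative zone
        self._alt_cache: dict = {}
        self.path_groups: dict[tuple[str, str], np.ndarray] = {}
        self.pair_index = np.empty(n, dtype=int)   # (layout, box) -> retrofit slot
        self.pair_keys: list[tuple[str, str]] = []

        pair_slot: dict[tuple[str, str], int] = {}
        for i, row in enumerate(self.cells.itertuples(index=False)):
            scene = experiment.scene_for(row.layout_id, row.wall)
            z = scene.zone(row.zone_id).as_array()
            b = scene.box(row.box_colour).as_array()
            self.zone_xy[i] = z
            self.box_xy[i] = b
            self.start_xy[i] = scene.start_zone.as_array()
            wall = scene.obscuring_wall
            if wall is not None:
                th = math.radians(wall_normal_toward(wall, b))
                self.wall_anchor[i] = wall.a.as_array()
                self.wall_normal[i] = (math.cos(th), math.sin(th))
            else:
                self.wall_anchor[i] = np.nan
                self.wall_normal[i] = np.nan
            akey = (row.layout_id, row.wall, row.zone_id)
            if akey not in self._alt_cache:
                self._alt_cache[akey] = default_alternative_zone(scene, row.zone_id)
            self.alt_dir[i] = bearing_between(scene.zone(self._alt_cache[akey]), b)
            pkey = (row.layout_id, row.box_colour)
            if pkey not in pair_slot:
                pair_slot[pkey] = len(self.pair_keys)
                self.pair_keys.append(pkey)
            self.pair_index[i] = pair_slot[pkey]
            self.path_groups.setdefault((row.layout_id, row.wall, row.zone_id, row.route), []).append(i)

        self.true_dir = _bearings(self.zone_xy, self.box_xy)
        self.box_dist = np.linalg.norm(self.box_xy - self.start_xy, axis=1)
        self.path_groups = {k: np.asarray(v, dtype=int) for k, v in self.path_groups.items()}
        self._path_steps: dict = {}
        for (layout_id, wall, zone_id, route) in self.path_groups:
            key = (zone_id, route)
            if key not in self._path_steps:
                path = experiment.path_for(layout_id, wall, zone_id, route)
                scene = experiment.scene_for(layout_id, wall)
                headings, lengths = _polyline_steps(path)
                h0 = float(scene.metadata.get("facing_bearing", headings[0]))
                self._path_steps[key] = (np.asarray(path[0], dtype=float), headings, lengths, h0)

    def __len__(self) -> int:
        return len(self.cells)

    def predict(self, model_id: str, params=None) -> np.ndarray:
        """Predicted pointing bearings (degrees) for every cell."""
        params = coerce_params(model_id, params)
        if model_id == "path_integration":
            return self._predict_path_integration(params)
        if model_id == "abathic":
            return self._predict_abathic(params)
        if model_id == "projection_plane":
            return self._predict_projection_plane(params)
        if model_id == "category_mixture":
            return self._predict_mixture(params)
        if model_id == "retrofit":
            return self._predict_retrofit(params)
        raise ValueError(f"unknown model {model_id!r}")

    def predicted_errors(self, model_id: str, params=None) -> np.ndarray:
        return signed_error(self.predict(model_id, params), self.true_dir)

    # -- per-model vectorised rules ------------------------------------

    def _predict_path_integration(self, params: PathIntegrationParams) -> np.ndarray:
        out = np.empty(len(self))
        for (layout_id, wall, zone_id, route), idxs in self.path_groups.items():
            start, headings, lengths, h0 = self._path_steps[(zone_id, route)]
            believed, herr = _integrate_path(start, headings, lengths, h0,
                                             params.translation_gain, params.rotation_gain)
            bear = _bearings(np.broadcast_to(believed, (len(idxs), 2)), self.box_xy[idxs])
            out[idxs] = wrap_angle(bear + herr)
        return out

    def _predict_abathic(self, params: AbathicParams) -> np.ndarray:
        d = self.box_dist
        d_prime = params.compression * d + (1.0 - params.compression) * params.abathic_distance
        remembered = self.box_xy + ((d_prime / d) - 1.0)[:, None] * (self.box_xy - self.start_xy)
        return _bearings(self.zone_xy, remembered)

    def _predict_projection_plane(self, params: ProjectionPlaneParams) -> np.ndarray:
        if np.any(~np.isfinite(self.wall_normal)):
            raise GeometryError("a design cell has no designated obscuring wall")
        n = self.wall_normal
        plane_pt = self.wall_anchor + params.plane_offset * n
        depth = np.einsum("ij,ij->i", self.box_xy - plane_pt, n)
        if params.mode == "orthogonal":
            proj = self.box_xy - depth[:, None] * n
        else:
            u = self.box_xy - self.start_xy
            u = u / np.linalg.norm(u, axis=1, keepdims=True)
            un = np.einsum("ij,ij->i", u, n)
            if np.any(np.abs(un) < 1e-12):
                raise ParallelLinesError("a sight-line is parallel to the projection plane")
            t = np.einsum("ij,ij->i", plane_pt - self.start_xy, n) / un
            if np.any(t < -COINCIDENT_TOL):
                raise BehindOriginError("a projection falls behind the start zone")
            proj = self.start_xy + t[:, None] * u
        return _bearings(self.zone_xy, proj)

    def _predict_mixture(self, params: MixtureParams) -> np.ndarray:
        if params.alternative_zone is not None:
            alt_dir = np.array([
                self.experiment.scene_for(r.layout_id, r.wall)
                .true_direction(params.alternative_zone, r.box_colour)
                for r in self.cells.itertuples(index=False)
            ])
        else:
            alt_dir = self.alt_dir
        w = params.w_actual
        a1 = np.radians(self.true_dir)
        a2 = np.radians(alt_dir)
        x = w * np.cos(a1) + (1.0 - w) * np.cos(a2)
        y = w * np.sin(a1) + (1.0 - w) * np.sin(a2)
        if np.any(np.hypot(x, y) < COINCIDENT_TOL):
            raise DegenerateGeometryError("mixture has no mean direction for some cell")
        return wrap_angle(np.degrees(np.arctan2(y, x)))

    def _predict_retrofit(self, params: RetrofitParams) -> np.ndarray:
        try:
            locs = np.array([np.asarray(params.locations[k], dtype=float) for k in self.pair_keys])
        except KeyError as err:
            raise ValueError(f"no remembered location for cell {err}") from None
        return _bearings(self.zone_xy, locs[self.pair_index])


def _integrate_path(start: np.ndarray, headings: np.ndarray, lengths: np.ndarray,
                    h0: float, translation_gain: float, rotation_gain: float):
    """Believed end position and heading error (actual − believed) for a path."""
    actual = h0
    believed_h = h0
    believed = np.array(start, dtype=float)
    for h_seg, length in zip(headings, lengths):
        turn = wrap_angle(h_seg - actual)
        actual += turn
        believed_h += rotation_gain * turn
        th = math.radians(believed_h)
        believed = believed + translation_gain * length * np.array([math.cos(th), math.sin(th)])
    return believed, wrap_angle(actual - believed_h)


def predict_table(experiment, model_id: str, params=None, predictor: CellPredictor | None = None
                  ) -> pd.DataFrame:
    """Model predictions for every unique design cell of an experiment.

    Returns one row per (layout, wall, route, zone, box) with the true
    bearing, the predicted bearing, and the predicted signed error, plus the
    model id and a textual dump of the parameters for provenance.
    """
    params = coerce_params(model_id, params)
    predictor = predictor or CellPredictor(experiment)
    preds = predictor.predict(model_id, params)
    out = predictor.cells.copy()
    out["true_direction_deg"] = predictor.true_dir
    out["predicted_direction_deg"] = preds
    out["predicted_error_deg"] = signed_error(preds, predictor.true_dir)
    out["model_id"] = model_id
    out["model_params"] = _params_repr(params)
    return out


def _params_repr(params) -> str:
    if isinstance(params, RetrofitParams):
        return f"retrofit[{len(params.locations)} locations]"
    return ",".join(f"{f.name}={getattr(params, f.name)}" for f in fields(params))
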