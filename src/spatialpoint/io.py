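"""File formats and reproducibility plumbing.

Pointing records travel as UTF-8 comma-delimited text with a header row and
angles in degrees, one shot per row — the same tabular shape the public
pointing datasets use, so external tables can be adapted with a simple
column-name mapping.  Scenes and run configurations are human-editable YAML
(metres and degrees only).  Every output directory gets a JSON manifest with
the config, the seeds, and checksums of the files written, which is enough
to reproduce the tables byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from importlib import metadata
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import PlanPoint, Scene, WallSegment, wrap_angle, signed_error

__all__ = [
    "PointingTableError",
    "REQUIRED_COLUMNS",
    "read_pointing_table",
    "write_pointing_table",
    "scene_to_dict",
    "scene_from_dict",
    "save_scene",
    "load_scene",
    "RunConfig",
    "load_config",
    "write_manifest",
]

REQUIRED_COLUMNS = [
    "participant_id", "experiment_id", "layout_id", "zone_id", "box_colour",
    "shot_index", "shot_direction_deg", "true_direction_deg",
]
ANGLE_COLUMNS = ["shot_direction_deg", "true_direction_deg", "signed_error_deg"]


class PointingTableError(ValueError):
    """A pointing-record file violated the schema; lists every offender."""


def write_pointing_table(records: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records.to_csv(path, index=False)
    return path


def read_pointing_table(path, column_map: dict[str, str] | None = None,
                        valid_zones=None, valid_boxes=None) -> pd.DataFrame:
    """Read and validate a pointing-record table.

    ``column_map`` renames external headers onto the package schema before
    validation.  All schema violations are collected and reported together
    with line numbers (header = line 1).  Out-of-range angles are wrapped to
    (−180, 180] with a warning; the signed error is always recomputed from
    the shot and true directions so the stored triple stays consistent.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    problems: list[str] = []
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        problems.append(f"missing required column(s): {', '.join(missing)}")
    for col in ANGLE_COLUMNS:
        if col not in df.columns:
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()]
        for i in bad[:20]:
            problems.append(f"line {i + 2}: unparsable angle {df.loc[i, col]!r} in {col}")
        df[col] = vals
        nan_rows = df.index[df[col].isna()]
        for i in nan_rows[:20]:
            problems.append(f"line {i + 2}: missing value in {col}")
    for col, valid in (("zone_id", valid_zones), ("box_colour", valid_boxes)):
        if valid is not None and col in df.columns:
            bad = df.index[~df[col].isin(list(valid))]
            for i in bad[:20]:
                problems.append(f"line {i + 2}: unknown {col} {df.loc[i, col]!r}")
    if problems:
        raise PointingTableError("invalid pointing table:\n  " + "\n  ".join(problems))

    for col in ("shot_direction_deg", "true_direction_deg"):
        vals = df[col].to_numpy(dtype=float)
        wrapped = wrap_angle(vals)
        n_out = int(np.sum(np.abs(vals - wrapped) > 1e-12))
        if n_out:
            warnings.warn(
                f"{n_out} value(s) in {col} were outside (-180, 180] and have been wrapped",
                stacklevel=2,
            )
            df[col] = wrapped
    df["signed_error_deg"] = signed_error(df["shot_direction_deg"].to_numpy(),
                                          df["true_direction_deg"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# scenes


def scene_to_dict(scene: Scene) -> dict:
    d = {
        "units": {"length": "metres", "angle": "degrees"},
        "start_zone": list(scene.start_zone),
        "pointing_zones": {k: list(v) for k, v in scene.pointing_zones.items()},
        "boxes": {k: list(v) for k, v in scene.boxes.items()},
        "walls": [
            {"a": list(w.a), "b": list(w.b), "label": w.label} for w in scene.walls
        ],
        "bounds": [list(scene.bounds[0]), list(scene.bounds[1])],
        "metadata": dict(scene.metadata),
    }
    if scene.obscuring_wall is not None:
        d["obscuring_wall"] = {
            "a": list(scene.obscuring_wall.a),
            "b": list(scene.obscuring_wall.b),
            "label": scene.obscuring_wall.label,
        }
    return d


def _wall_from_dict(d: dict) -> WallSegment:
    return WallSegment(PlanPoint(*d["a"]), PlanPoint(*d["b"]), d.get("label", ""))


def scene_from_dict(d: dict) -> Scene:
    return Scene(
        start_zone=PlanPoint(*d["start_zone"]),
        pointing_zones={k: PlanPoint(*v) for k, v in d["pointing_zones"].items()},
        boxes={k: PlanPoint(*v) for k, v in d["boxes"].items()},
        walls=[_wall_from_dict(w) for w in d.get("walls", [])],
        obscuring_wall=_wall_from_dict(d["obscuring_wall"]) if "obscuring_wall" in d else None,
        bounds=tuple(tuple(b) for b in d.get("bounds", ((-3, 3), (-3, 3)))),
        metadata=dict(d.get("metadata", {})),
    )


def save_scene(scene: Scene, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(scene_to_dict(scene), sort_keys=False))
    return path


def load_scene(path) -> Scene:
    return scene_from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# run configuration and manifest


@dataclass
class RunConfig:
    """Everything that determines a simulation/fit run."""

    preset: str = "exp1"
    n_layouts: int | None = None
    layout_seed: int = 0
    generator: str = "projection_plane"
    generator_params: dict = field(default_factory=dict)
    noise_family: str = "wrapped_gaussian"
    noise_sd_deg: float = 8.0
    n_participants: int = 20
    between_participant_sd: float = 0.0
    models: list[str] = field(default_factory=lambda: [
        "path_integration", "abathic", "retrofit", "projection_plane", "category_mixture",
    ])
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(out_dir, config: dict, seeds: dict, outputs: list) -> Path:
    """JSON manifest: config echo, package version, seeds, file checksums."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        version = metadata.version("spatialpoint")
    except metadata.PackageNotFoundError:  # running from a source tree
        version = "unknown"
    cfg_json = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "package": "spatialpoint",
        "version": version,
        "config": config,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seeds": seeds,
        "outputs": [
            {"path": str(Path(p).relative_to(out_dir)), "sha256": _sha256(Path(p))}
            for p in outputs
        ],
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
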