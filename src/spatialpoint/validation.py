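"""Self-consistency analyses of the modelling pipeline.

The headline fits of a real dataset depend on that dataset; what the package
can and does guarantee is structural: each candidate model, used as a
generator, is identified back by the model comparison on its own synthetic
data; the retrofit triangulation recovers known target locations to within
the sampling error of the shots; the projection-plane rule stays between the
true target bearing and the wall normal on randomised scenes; and paired
wall-orientation differences behave like the study's — biased against ground
truth, centred on zero against the generating model's own predictions.

These drivers are used both by the test suite and by the acceptance script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import designs, models, simulate, stats
from .geometry import wall_normal_toward, wrap_angle
from .models import MODEL_IDS, RetrofitParams
from .noise import NoiseSpec

__all__ = [
    "model_recovery_matrix",
    "retrofit_location_recovery",
    "veridical_limit_deviations",
    "projection_betweenness",
    "exp4_paired_analysis",
    "exp1_condition_consistency",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) & 0x7FFFFFFF for s in np.random.SeedSequence(seed).generate_state(n)]


def model_recovery_matrix(seed: int = 0, n_replicates: int = 20, n_participants: int = 6,
                          n_layouts: int = 4, noise: NoiseSpec = NoiseSpec(sd_deg=8.0),
                          retrofit_grid_resolution: float = 0.2) -> pd.DataFrame:
    """BIC model-recovery matrix on synthetic cohorts of the direct/indirect design.

    For every generator, ``n_replicates`` cohorts are simulated and all five
    models fitted; a replicate counts as a win when the generator attains the
    lowest BIC.  Returns a tidy frame with one row per (generator, winner)
    pair plus a ``win_rate`` per generator.
    """
    exp = designs.exp1(n_layouts=n_layouts, seed=seed)
    rows = []
    seeds = _child_seeds(seed, n_replicates * len(MODEL_IDS))
    i = 0
    for gen in MODEL_IDS:
        for rep in range(n_replicates):
            rec = simulate.participant_cohort(exp, n_participants, gen, noise=noise,
                                              seed=seeds[i])
            i += 1
            fits = [
                stats.fit_model(rec, exp, mid, noise=noise, seed=seed,
                                retrofit_grid_resolution=retrofit_grid_resolution)
                for mid in MODEL_IDS
            ]
            winner = min(fits, key=lambda f: f.bic)
            rows.append({"generator": gen, "replicate": rep, "winner": winner.model_id,
                         "won": winner.model_id == gen})
    out = pd.DataFrame(rows)
    out["win_rate"] = out.groupby("generator")["won"].transform("mean")
    return out


def retrofit_location_recovery(seed: int = 0, n_replicates: int = 100,
                               noise: NoiseSpec = NoiseSpec(sd_deg=8.0),
                               zones: tuple[str, ...] = ("A", "B", "C"),
                               shots_per_box: int = 8,
                               grid_resolution: float = 0.1) -> np.ndarray:
    """Euclidean errors (metres) of ML target locations on synthetic shots.

    Shots are generated around the true box locations from ``zones`` with
    independent angular noise; each replicate retrofits all four boxes of one
    layout.  Returns the pooled per-box location errors.
    """
    exp = designs.exp1(n_layouts=1, seed=seed)
    exp.design = designs.enumerate_trials(
        "exp1", 1, zones_by_route={"indirect": zones}, shots_per_box=shots_per_box
    )
    scene = exp.scene_for("L1", "EW")
    truth = {("L1", c): scene.boxes[c] for c in scene.boxes}
    errors = []
    for rep_seed in _child_seeds(seed, n_replicates):
        rec = simulate.simulate_pointing(exp, "retrofit", RetrofitParams(locations=truth),
                                         noise=noise, seed=rep_seed)
        rf = models.retrofit_targets(rec, exp, noise=noise, grid_resolution=grid_resolution,
                                     store_surfaces=False)
        for key, p in rf.ml_locations.items():
            t = truth[key]
            errors.append(float(np.hypot(p.x - t.x, p.y - t.y)))
    return np.asarray(errors)


def veridical_limit_deviations(seed: int = 0) -> dict[str, float]:
    """Maximum |predicted − true| bearing (degrees) in each model's veridical limit.

    Unit gains, no compression, unit mixture weight, and — for the
    projection plane — a target placed exactly on the plane must all
    reproduce the true direction; the retrofit limit (noiseless shots from
    three zones through one point) is reported as the bearing error of the
    recovered location.
    """
    exp = designs.exp1(n_layouts=2, seed=seed)
    pred = models.CellPredictor(exp)
    out = {}
    out["path_integration"] = float(np.max(np.abs(pred.predicted_errors(
        "path_integration", {"translation_gain": 1.0, "rotation_gain": 1.0}))))
    out["abathic"] = float(np.max(np.abs(pred.predicted_errors(
        "abathic", {"compression": 1.0}))))
    out["category_mixture"] = float(np.max(np.abs(pred.predicted_errors(
        "category_mixture", {"w_actual": 1.0}))))

    # projection plane: move each box onto the plane, then predict
    worst = 0.0
    for (lid, wall), scene in exp.scenes.items():
        for colour in scene.boxes:
            params = models.ProjectionPlaneParams()
            on_plane = models.projected_box(scene, colour, params)
            moved = scene.boxes | {colour: on_plane}
            from dataclasses import replace
            sc2 = replace(scene, boxes=moved)
            for zone in sc2.pointing_zones:
                dev = wrap_angle(models.predict_projection_plane(sc2, zone, colour, params)
                                 - sc2.true_direction(zone, colour))
                worst = max(worst, abs(dev))
    out["projection_plane"] = worst

    # retrofit: noiseless consistent shots triangulate back to the point
    exp1 = designs.exp1(n_layouts=1, seed=seed)
    exp1.design = designs.enumerate_trials(
        "exp1", 1, zones_by_route={"indirect": ("A", "B", "C")}, shots_per_box=2
    )
    scene = exp1.scene_for("L1", "EW")
    truth = {("L1", c): scene.boxes[c] for c in scene.boxes}
    rec = simulate.simulate_pointing(exp1, "retrofit", RetrofitParams(locations=truth),
                                     noise=None)
    rf = models.retrofit_targets(rec, exp1, grid_resolution=0.1, store_surfaces=False)
    worst = 0.0
    for key, p in rf.ml_locations.items():
        t = truth[key]
        for zone in scene.pointing_zones:
            from .geometry import bearing_between
            dev = wrap_angle(bearing_between(scene.zone(zone), p)
                             - bearing_between(scene.zone(zone), t))
            worst = max(worst, abs(dev))
    out["retrofit"] = worst
    return out


def projection_betweenness(seed: int = 0, n_scenes: int = 1000) -> dict:
    """Count violations of the 'between true direction and wall normal' property.

    Over randomised scenes with the target between the obscuring wall and
    the projection plane, the projection-plane prediction must lie in the
    closed angular interval spanned by the true target bearing and the
    wall-normal bearing, as seen from the pointing zone.
    """
    rng = np.random.default_rng(seed)
    violations = 0
    max_ratio = -np.inf
    min_ratio = np.inf
    for _ in range(n_scenes):
        scene, zone, box = designs.sample_projection_scene(rng)
        true = scene.true_direction(zone, box)
        pred = models.predict_projection_plane(scene, zone, box)
        normal = wall_normal_toward(scene.obscuring_wall, scene.box(box))
        d_pred = wrap_angle(pred - true)
        d_norm = wrap_angle(normal - true)
        ratio = d_pred / d_norm if d_norm != 0.0 else 0.0
        max_ratio = max(max_ratio, ratio)
        min_ratio = min(min_ratio, ratio)
        if not (-1e-9 <= ratio <= 1.0 + 1e-9):
            violations += 1
    return {"n_scenes": n_scenes, "violations": violations,
            "min_ratio": float(min_ratio), "max_ratio": float(max_ratio)}


def exp4_paired_analysis(seed: int = 0, n_participants: int = 10,
                         noise: NoiseSpec = NoiseSpec(sd_deg=8.0),
                         zones: tuple[str, ...] = ("C", "E")) -> dict:
    """Paired wall-orientation differences on projection-plane-generated data.

    Returns, per mirrored zone, the one-sample test of the differences taken
    against ground truth (expected: significantly nonzero, opposite signs
    across the mirrored zones, sign-consistent within a zone) and, pooled,
    the test of differences taken against the generating model's own
    predictions (expected: mean within sampling error of zero).
    """
    exp = designs.exp4(seed=seed)
    rec = simulate.participant_cohort(exp, n_participants, "projection_plane",
                                      noise=noise, seed=seed)
    vs_truth = stats.paired_wall_differences(rec)
    result = {"per_zone": {}}
    for z in zones:
        d = vs_truth.loc[vs_truth["zone_id"] == z, "delta_deg"].to_numpy()
        t = stats.one_sample_t(d)
        result["per_zone"][z] = {
            "test": t,
            "sign_consistency": float(max((d > 0).mean(), (d < 0).mean())),
        }
    pred = models.predict_table(exp, "projection_plane")
    vs_model = stats.paired_wall_differences(rec, reference="model_prediction",
                                             predictions=pred)
    d = vs_model["delta_deg"].to_numpy()
    result["vs_model"] = {
        "test": stats.one_sample_t(d),
        "se": float(np.std(d, ddof=1) / np.sqrt(d.size)),
    }
    return result


def exp1_condition_consistency(seed: int = 0, n_participants: int = 20,
                               n_layouts: int = 4,
                               noise: NoiseSpec = NoiseSpec(sd_deg=8.0)) -> dict:
    """Direct-versus-indirect consistency of cell-mean errors, study style.

    Simulates a cohort with the projection-plane generator (whose
    predictions do not depend on the walking route), then correlates the
    per-(layout, zone, box) mean errors of the direct and indirect arms for
    the zones tested under both, and tests the per-zone signed errors
    against zero.
    """
    exp = designs.exp1(n_layouts=n_layouts, seed=seed)
    rec = simulate.participant_cohort(exp, n_participants, "projection_plane",
                                      noise=noise, seed=seed)
    cells = stats.mean_errors_by_cell(
        rec, keys=["route", "layout_id", "zone_id", "box_colour"]
    )
    wide = cells.pivot_table(index=["layout_id", "zone_id", "box_colour"],
                             columns="route", values="mean_error_deg").dropna()
    r, slope = stats.condition_correlation(wide["direct"], wide["indirect"])
    zone_tests = {}
    for zgroup, label in ((("A", "B"), "AB"), (("C",), "C")):
        vals = rec.loc[rec["zone_id"].isin(zgroup), "signed_error_deg"].to_numpy()
        zone_tests[label] = stats.one_sample_t(vals)
    return {"r": r, "slope": slope, "n_pairs": int(len(wide)), "zone_tests": zone_tests}
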