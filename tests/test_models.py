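"""The five candidate pointing models and their documented limits."""

import math
from dataclasses import replace

import numpy as np
import pytest

from spatialpoint import designs, simulate
from spatialpoint.geometry import (
    PlanPoint,
    Scene,
    WallSegment,
    bearing_between,
    transform_scene,
    wrap_angle,
)
from spatialpoint.models import (
    MODEL_IDS,
    AbathicParams,
    CellPredictor,
    IdentifiabilityError,
    MixtureParams,
    PathIntegrationParams,
    ProjectionPlaneParams,
    RetrofitParams,
    coerce_params,
    default_alternative_zone,
    predict_abathic,
    predict_category_mixture,
    predict_direction,
    predict_path_integration,
    predict_projection_plane,
    retrofit_targets,
)
from spatialpoint.noise import NoiseSpec


def _simple_scene(**kw):
    defaults = dict(
        start_zone=PlanPoint(0, 0),
        pointing_zones={"Z": PlanPoint(0, -3)},
        boxes={"blue": PlanPoint(6, 0)},
        walls=[],
        obscuring_wall=None,
        bounds=((-10, 10), (-10, 10)),
    )
    defaults.update(kw)
    return Scene(**defaults)


class TestPathIntegration:
    def test_unit_gains_reproduce_true_direction(self, exp1_small):
        pred = CellPredictor(exp1_small)
        err = pred.predicted_errors("path_integration",
                                    PathIntegrationParams(1.0, 1.0))
        assert np.max(np.abs(err)) < 1e-9

    def test_translation_undershoot_on_straight_path(self):
        """Believed position falls short: hand-computed atan2(5, 1) = 78.69°."""
        scene = _simple_scene(pointing_zones={"Z": PlanPoint(10, 0)},
                              boxes={"blue": PlanPoint(10, 5)})
        path = [(0, 0), (10, 0)]
        out = predict_path_integration(scene, path, "Z", "blue",
                                       PathIntegrationParams(translation_gain=0.9))
        assert out == pytest.approx(math.degrees(math.atan2(5, 1)), abs=1e-9)

    def test_rotation_gain_misattributes_heading(self):
        """A 90° turn believed as 81° leaves a +9° executed offset plus the
        displaced believed position."""
        scene = _simple_scene(pointing_zones={"Z": PlanPoint(5, 5)},
                              boxes={"blue": PlanPoint(10, 0)},
                              metadata={"facing_bearing": 0.0})
        path = [(0, 0), (5, 0), (5, 5)]
        out = predict_path_integration(scene, path, "Z", "blue",
                                       PathIntegrationParams(rotation_gain=0.9))
        # believed: walk 5 East, turn believed 81°, walk 5 -> (5.78, 4.94)
        bx = 5 + 5 * math.cos(math.radians(81))
        by = 5 * math.sin(math.radians(81))
        expected = wrap_angle(math.degrees(math.atan2(0 - by, 10 - bx)) + (90 - 81))
        assert out == pytest.approx(expected, abs=1e-9)

    def test_longer_path_gives_larger_bias(self, exp1_small):
        params = PathIntegrationParams(translation_gain=0.85, rotation_gain=0.9)
        scene = exp1_small.scene_for("L1", "EW")
        errs = {}
        for route in ("direct", "indirect"):
            path = exp1_small.path_for("L1", "EW", "C", route)
            out = predict_path_integration(scene, path, "C", "blue", params)
            errs[route] = abs(wrap_angle(out - scene.true_direction("C", "blue")))
        assert errs["indirect"] > errs["direct"]

    def test_degenerate_paths_raise(self, exp1_small):
        scene = exp1_small.scene_for("L1", "EW")
        with pytest.raises(Exception):
            predict_path_integration(scene, [(0, -2.2)], "A", "blue")
        with pytest.raises(Exception):  # does not end at the zone
            predict_path_integration(scene, [(0, -2.2), (1, 1)], "A", "blue")


class TestAbathic:
    def test_no_compression_is_identity(self, exp1_small):
        scene = exp1_small.scene_for("L1", "EW")
        for zone in scene.pointing_zones:
            for colour in scene.boxes:
                out = predict_abathic(scene, zone, colour, AbathicParams(compression=1.0))
                assert out == scene.true_direction(zone, colour)

    def test_abathic_distance_is_a_fixed_point(self):
        scene = _simple_scene(boxes={"blue": PlanPoint(4, 0)})
        for c in (0.3, 0.7):
            out = predict_abathic(scene, "Z", "blue",
                                  AbathicParams(abathic_distance=4.0, compression=c))
            assert out == pytest.approx(scene.true_direction("Z", "blue"), abs=1e-12)

    def test_hand_computed_compression(self):
        """d=6 compressed about a=2 with c=0.5 -> remembered at 4 m; from
        (0,−3) that is atan2(3, 4) = 36.87°."""
        scene = _simple_scene()
        out = predict_abathic(scene, "Z", "blue", AbathicParams(2.0, 0.5))
        assert out == pytest.approx(math.degrees(math.atan2(3, 4)), abs=1e-9)

    def test_invalid_params_raise(self):
        with pytest.raises(ValueError):
            AbathicParams(abathic_distance=-1.0)
        with pytest.raises(ValueError):
            AbathicParams(compression=0.0)


class TestProjectionPlane:
    def test_box_on_plane_predicts_true_direction(self):
        wall = WallSegment(PlanPoint(-5, 2), PlanPoint(5, 2))
        scene = _simple_scene(boxes={"blue": PlanPoint(1.0, 3.77)},
                              pointing_zones={"Z": PlanPoint(-2, 0)},
                              walls=[wall], obscuring_wall=wall)
        out = predict_projection_plane(scene, "Z", "blue")
        assert out == scene.true_direction("Z", "blue")

    def test_worked_example_33_16_degrees(self):
        """Wall y=2, offset 1.77: box (4,4) projects along the start-zone ray
        to (3.77, 3.77); from zone (−2, 0) the bearing is 33.16°."""
        wall = WallSegment(PlanPoint(-5, 2), PlanPoint(5, 2))
        scene = _simple_scene(boxes={"blue": PlanPoint(4, 4)},
                              pointing_zones={"Z": PlanPoint(-2, 0)},
                              walls=[wall], obscuring_wall=wall)
        out = predict_projection_plane(scene, "Z", "blue")
        assert out == pytest.approx(math.degrees(math.atan2(3.77, 5.77)), abs=1e-9)

    def test_orthogonal_variant_differs_from_sightline(self):
        wall = WallSegment(PlanPoint(-5, 2), PlanPoint(5, 2))
        scene = _simple_scene(boxes={"blue": PlanPoint(4, 4)},
                              pointing_zones={"Z": PlanPoint(-2, 0)},
                              walls=[wall], obscuring_wall=wall)
        sight = predict_projection_plane(scene, "Z", "blue", ProjectionPlaneParams())
        orth = predict_projection_plane(scene, "Z", "blue",
                                        ProjectionPlaneParams(mode="orthogonal"))
        assert sight != orth
        # orthogonal drop of (4,4) onto y=3.77 is (4, 3.77)
        assert orth == pytest.approx(math.degrees(math.atan2(3.77, 6.0)), abs=1e-9)

    def test_rigid_motion_equivariance(self, exp1_small):
        scene = exp1_small.scene_for("L2", "EW")
        angle, offset = 27.0, (5.0, -4.0)
        moved = transform_scene(scene, angle, offset)
        for zone in ("A", "C"):
            for colour in ("blue", "yellow"):
                p0 = predict_projection_plane(scene, zone, colour)
                p1 = predict_projection_plane(moved, zone, colour)
                assert wrap_angle(p1 - p0) == pytest.approx(angle, abs=1e-9)

    def test_missing_wall_raises(self):
        scene = _simple_scene()
        with pytest.raises(Exception):
            predict_projection_plane(scene, "Z", "blue")

    def test_prediction_between_truth_and_wall_normal(self, exp1_small):
        """With the zone laterally clear of the projected-target fan (as in
        the direct/indirect design), the prediction never overshoots the
        wall-normal direction."""
        from spatialpoint.geometry import wall_normal_toward

        pred = CellPredictor(exp1_small)
        t = pred.predict("projection_plane", None)
        for i, row in enumerate(pred.cells.itertuples(index=False)):
            scene = exp1_small.scene_for(row.layout_id, row.wall)
            normal = wall_normal_toward(scene.obscuring_wall, scene.box(row.box_colour))
            d_pred = wrap_angle(t[i] - pred.true_dir[i])
            d_norm = wrap_angle(normal - pred.true_dir[i])
            ratio = d_pred / d_norm
            assert -1e-9 <= ratio <= 1 + 1e-9


class TestCategoryMixture:
    def test_unit_weight_is_true_direction(self, exp1_small):
        scene = exp1_small.scene_for("L1", "EW")
        out = predict_category_mixture(scene, "C", "blue", MixtureParams(w_actual=1.0))
        assert out == scene.true_direction("C", "blue")

    def test_resultant_vector_mean_of_0_and_90(self):
        scene = _simple_scene(
            pointing_zones={"Z": PlanPoint(0, 0), "ALT": PlanPoint(6, -6)},
            boxes={"blue": PlanPoint(6, 0)},
        )
        # from Z the box is at 0°, from ALT at 90°
        out = predict_category_mixture(scene, "Z", "blue",
                                       MixtureParams(0.82, alternative_zone="ALT"))
        assert out == pytest.approx(math.degrees(math.atan2(0.18, 0.82)), abs=1e-9)

    def test_antipodal_equal_weights_is_undefined(self):
        scene = _simple_scene(
            pointing_zones={"Z": PlanPoint(-6, 0), "ALT": PlanPoint(12, 0)},
            boxes={"blue": PlanPoint(6, 0)},
        )
        with pytest.raises(Exception):
            predict_category_mixture(scene, "Z", "blue",
                                     MixtureParams(0.5, alternative_zone="ALT"))

    def test_default_alternative_zone_is_nearest_opposite_side(self, exp1_small):
        scene = exp1_small.scene_for("L1", "EW")
        # C is East of the sight axis; B is the laterally nearest western zone
        assert default_alternative_zone(scene, "C") == "B"
        assert default_alternative_zone(scene, "A") == "C"

    def test_default_weight_is_0p82(self):
        assert MixtureParams().w_actual == 0.82


class TestRetrofit:
    def test_noiseless_triangulation_recovers_the_point(self, exp1_small, noise8):
        exp = designs.exp1(n_layouts=1, seed=0)
        exp.design = designs.enumerate_trials(
            "exp1", 1, zones_by_route={"indirect": ("A", "B", "C")}, shots_per_box=2
        )
        scene = exp.scene_for("L1", "EW")
        truth = {("L1", c): scene.boxes[c] for c in scene.boxes}
        rec = simulate.simulate_pointing(exp, "retrofit", RetrofitParams(truth), noise=None)
        rf = retrofit_targets(rec, exp, noise=noise8, grid_resolution=0.1)
        for key, p in rf.ml_locations.items():
            t = truth[key]
            assert math.dist(p, t) < 0.1  # within one grid cell
            g = rf.grid_argmax[key]
            assert math.dist(p, g) <= 0.1 * math.sqrt(2) + 1e-9

    def test_single_zone_input_is_unidentifiable(self, noise8):
        exp = designs.exp1(n_layouts=1, seed=0)
        exp.design = designs.enumerate_trials(
            "exp1", 1, zones_by_route={"indirect": ("A",)}, shots_per_box=4
        )
        rec = simulate.simulate_pointing(exp, "projection_plane", noise=noise8)
        with pytest.raises(IdentifiabilityError):
            retrofit_targets(rec, exp, noise=noise8)

    def test_empty_records_raise(self, exp1_small, noise8):
        import pandas as pd

        with pytest.raises(ValueError):
            retrofit_targets(pd.DataFrame(), exp1_small, noise=noise8)

    def test_parameter_count_is_two_per_location(self, exp1_small, noise8):
        rec = simulate.simulate_pointing(exp1_small, "projection_plane", noise=noise8, seed=0)
        rf = retrofit_targets(rec, exp1_small, noise=noise8, grid_resolution=0.3,
                              refine=False, store_surfaces=False)
        assert rf.n_parameters == 2 * len(rf.ml_locations) == 2 * 4 * 4

    def test_grid_argmax_matches_double_resolution_brute_force(self, noise8):
        exp = designs.exp1(n_layouts=1, seed=1)
        exp.design = designs.enumerate_trials(
            "exp1", 1, zones_by_route={"indirect": ("A", "B", "C")}, shots_per_box=4
        )
        rec = simulate.simulate_pointing(exp, "projection_plane", noise=noise8, seed=5)
        coarse = retrofit_targets(rec, exp, noise=noise8, grid_resolution=0.2, refine=False)
        fine = retrofit_targets(rec, exp, noise=noise8, grid_resolution=0.1, refine=False)
        for key in coarse.ml_locations:
            assert math.dist(coarse.ml_locations[key], fine.ml_locations[key]) <= 0.2 * 1.5


class TestDispatch:
    def test_cell_predictor_agrees_with_scalar_reference(self, exp4_preset):
        pred = CellPredictor(exp4_preset)
        cases = {
            "path_integration": PathIntegrationParams(0.8, 0.9),
            "abathic": AbathicParams(3.0, 0.6),
            "projection_plane": ProjectionPlaneParams(),
            "category_mixture": MixtureParams(0.82),
        }
        for mid, params in cases.items():
            vec = pred.predict(mid, params)
            for i, row in enumerate(pred.cells.itertuples(index=False)):
                scalar = predict_direction(exp4_preset, mid, params, row.layout_id,
                                           row.wall, row.route, row.zone_id, row.box_colour)
                assert vec[i] == pytest.approx(scalar, abs=1e-9)

    def test_coerce_params_accepts_dicts_and_rejects_junk(self):
        p = coerce_params("abathic", {"abathic_distance": 2.0})
        assert isinstance(p, AbathicParams) and p.compression == 0.6
        with pytest.raises(ValueError):
            coerce_params("nonsense", None)
        with pytest.raises(TypeError):
            coerce_params("abathic", 3.0)
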