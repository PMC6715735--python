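"""Circular means, correlations, t-tests, paired differences, model scoring."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from spatialpoint import models, simulate, stats
from spatialpoint.noise import NoiseSpec
from spatialpoint.stats import (
    PairingError,
    circular_mean,
    compare_models,
    condition_correlation,
    fit_model,
    mean_errors_by_cell,
    one_sample_t,
    paired_wall_differences,
)


class TestCircularMean:
    @pytest.mark.parametrize(
        "values, expected",
        [([5] * 8, 5.0), ([10, -10], 0.0), ([179, -179], 180.0)],
    )
    def test_wrap_aware_examples(self, values, expected):
        assert circular_mean(values) == pytest.approx(expected, abs=1e-9)

    @given(st.lists(st.floats(-180, 180), min_size=1, max_size=30))
    def test_agrees_with_scipy_circmean(self, values):
        """Independent oracle: scipy's circular mean mapped to (−180, 180]."""
        ours = circular_mean(values)
        theirs = float(sps.circmean(np.asarray(values), high=180.0, low=-180.0))
        from spatialpoint.geometry import wrap_angle

        assert abs(wrap_angle(ours - theirs)) < 1e-7

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            circular_mean([])


class TestMeanErrorsByCell:
    def test_cells_are_circular_means(self, exp1_small):
        rec = simulate.simulate_pointing(exp1_small, "projection_plane",
                                         noise=NoiseSpec(sd_deg=20.0), seed=0)
        out = mean_errors_by_cell(rec, keys=["layout_id", "zone_id", "box_colour"])
        one = rec[(rec.layout_id == "L1") & (rec.zone_id == "A") & (rec.box_colour == "blue")]
        expected = circular_mean(one["signed_error_deg"])
        got = out[(out.layout_id == "L1") & (out.zone_id == "A") & (out.box_colour == "blue")]
        assert got["mean_error_deg"].iloc[0] == pytest.approx(expected)
        assert got["n_shots"].iloc[0] == len(one)

    def test_missing_values_are_dropped_not_fatal(self, exp1_small, caplog):
        rec = simulate.simulate_pointing(exp1_small, "projection_plane", seed=0)
        rec.loc[rec.index[:5], "signed_error_deg"] = np.nan
        with caplog.at_level("WARNING"):
            out = mean_errors_by_cell(rec, keys=["zone_id"])
        assert "dropping 5" in caplog.text
        assert len(out) == rec["zone_id"].nunique()


class TestConditionCorrelation:
    def test_identity_line(self):
        x = np.arange(5.0)
        assert condition_correlation(x, x) == pytest.approx((1.0, 1.0))

    def test_exact_linear_map(self):
        x = np.arange(5.0)
        r, slope = condition_correlation(x, 2 * x + 1)
        assert (r, slope) == pytest.approx((1.0, 2.0))

    def test_closed_form_least_squares(self):
        """Hand oracle: x=(0,1,2,3), y=(0,1,1,2) -> slope 0.6, r = 3/sqrt(10)."""
        r, slope = condition_correlation([0, 1, 2, 3], [0, 1, 1, 2])
        assert slope == pytest.approx(0.6, abs=1e-12)
        assert r == pytest.approx(3 / math.sqrt(10), abs=1e-12)

    @given(st.lists(st.tuples(st.floats(-50, 50), st.floats(-50, 50)),
                    min_size=3, max_size=20))
    def test_agrees_with_independent_formula(self, pairs):
        x = np.array([p[0] for p in pairs])
        y = np.array([p[1] for p in pairs])
        if np.ptp(x) < 1e-6 or np.std(y) < 1e-9:
            return
        r, slope = condition_correlation(x, y)
        # brute-force normal-equation slope and definitional r
        xc, yc = x - x.mean(), y - y.mean()
        assert slope == pytest.approx(float(xc @ yc / (xc @ xc)), abs=1e-8)
        assert r == pytest.approx(float(xc @ yc / math.sqrt((xc @ xc) * (yc @ yc))), abs=1e-8)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            condition_correlation([1, 1, 1], [0, 1, 2])
        with pytest.raises(ValueError):
            condition_correlation([0, 1], [0, 1])


class TestOneSampleT:
    def test_null_case(self):
        res = one_sample_t([-1.0, 1.0, -2.0, 2.0])
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_summary_matches_raw_values(self):
        rng = np.random.default_rng(0)
        v = rng.normal(3, 10, size=47)
        raw = one_sample_t(v)
        summ = one_sample_t(mean=float(np.mean(v)), sd=float(np.std(v, ddof=1)), n=47)
        assert raw.t == pytest.approx(summ.t, abs=1e-9)
        assert raw.p == pytest.approx(summ.p, abs=1e-9)

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(1)
        v = rng.normal(2, 5, size=30)
        ours = one_sample_t(v)
        ref = sps.ttest_1samp(v, 0.0)
        assert ours.t == pytest.approx(ref.statistic, abs=1e-9)
        assert ours.p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_degenerate_sd_raises(self):
        with pytest.raises(ValueError):
            one_sample_t(mean=1.0, sd=0.0, n=10)


class TestPairedWallDifferences:
    def test_identical_conditions_give_zero_deltas(self, exp4_preset):
        rec = simulate.simulate_pointing(exp4_preset, "category_mixture",
                                         {"w_actual": 1.0}, noise=None)
        # truth generator: both wall conditions produce identical errors (all zero)
        out = paired_wall_differences(rec)
        assert np.allclose(out["delta_deg"], 0.0, atol=1e-9)

    def test_unpaired_trials_raise_with_offenders(self, exp4_preset):
        rec = simulate.simulate_pointing(exp4_preset, "projection_plane",
                                         noise=NoiseSpec(sd_deg=8.0), seed=0)
        broken = rec[~((rec.wall == "NW") & (rec.layout_id == "L1"))]
        with pytest.raises(PairingError):
            paired_wall_differences(broken)

    def test_model_reference_needs_predictions(self, exp4_preset):
        rec = simulate.simulate_pointing(exp4_preset, "projection_plane",
                                         noise=NoiseSpec(sd_deg=8.0), seed=0)
        with pytest.raises(ValueError):
            paired_wall_differences(rec, reference="model_prediction")

    def test_deltas_vs_generating_model_are_centred_on_zero(self, exp4_preset):
        """320 pairs per zone, σ=8°: residual differences against the
        generating model's predictions have |mean| within sampling error."""
        rec = simulate.participant_cohort(exp4_preset, 10, "projection_plane",
                                          noise=NoiseSpec(sd_deg=8.0), seed=11)
        pred = models.predict_table(exp4_preset, "projection_plane")
        out = paired_wall_differences(rec, reference="model_prediction", predictions=pred)
        d = out["delta_deg"].to_numpy()
        assert abs(d.mean()) < 1.5
        assert abs(d.mean()) < 3 * d.std(ddof=1) / math.sqrt(d.size)


class TestFitAndCompare:
    def test_information_criteria_identities(self, exp1_small, noise8):
        rec = simulate.simulate_pointing(exp1_small, "abathic", noise=noise8, seed=0)
        f = fit_model(rec, exp1_small, "abathic", noise=noise8, seed=0, n_restarts=2)
        assert f.aic == pytest.approx(2 * f.k - 2 * f.log_likelihood, abs=1e-9)
        assert f.bic == pytest.approx(f.k * math.log(f.n_obs) - 2 * f.log_likelihood, abs=1e-9)
        assert f.rmse >= 0 and abs(f.pearson_r) <= 1

    def test_bic_arithmetic_oracle(self):
        from spatialpoint.stats import _information_criteria

        aic, bic = _information_criteria(k=24, n=320, lnl=-100.0)
        assert bic == pytest.approx(24 * math.log(320) + 200, abs=1e-9)
        assert aic == pytest.approx(248.0, abs=1e-12)

    def test_projection_plane_has_zero_free_parameters(self, exp1_small, noise8):
        rec = simulate.simulate_pointing(exp1_small, "projection_plane", noise=noise8, seed=1)
        f = fit_model(rec, exp1_small, "projection_plane", noise=noise8)
        assert f.k == 0
        assert f.aic == pytest.approx(-2 * f.log_likelihood)

    def test_abathic_parameter_recovery(self, exp1_small):
        """Generator (a=3, c=0.6, σ=4°) recovered within ±0.5 m and ±0.1."""
        noise = NoiseSpec(sd_deg=4.0)
        gaps_a, gaps_c = [], []
        for seed in range(5):
            rec = simulate.participant_cohort(
                exp1_small, 4, "abathic", params={"abathic_distance": 3.0, "compression": 0.6},
                noise=noise, seed=seed,
            )
            f = fit_model(rec, exp1_small, "abathic", noise=noise, seed=seed)
            gaps_a.append(abs(f.params.abathic_distance - 3.0))
            gaps_c.append(abs(f.params.compression - 0.6))
        assert np.median(gaps_a) < 0.5
        assert np.median(gaps_c) < 0.1

    def test_nonsense_model_or_empty_records_raise(self, exp1_small, noise8):
        rec = simulate.simulate_pointing(exp1_small, "abathic", noise=noise8, seed=0)
        with pytest.raises(ValueError):
            fit_model(rec, exp1_small, "homing_vector", noise=noise8)
        with pytest.raises(ValueError):
            fit_model(rec.iloc[:0], exp1_small, "abathic", noise=noise8)

    def test_single_model_comparison_has_zero_deltas(self, exp1_small, noise8):
        rec = simulate.simulate_pointing(exp1_small, "projection_plane", noise=noise8, seed=2)
        f = fit_model(rec, exp1_small, "projection_plane", noise=noise8)
        rep = compare_models([f])
        assert rep["delta_bic"].iloc[0] == 0.0 and rep["delta_aic"].iloc[0] == 0.0

    def test_mismatched_fits_cannot_be_compared(self, exp1_small, noise8):
        rec = simulate.simulate_pointing(exp1_small, "projection_plane", noise=noise8, seed=2)
        f1 = fit_model(rec, exp1_small, "projection_plane", noise=noise8)
        f2 = fit_model(rec.iloc[: len(rec) // 2], exp1_small, "projection_plane", noise=noise8)
        with pytest.raises(ValueError):
            compare_models([f1, f2])

    def test_shots_mode_uses_shot_counts(self, exp1_small, noise8):
        rec = simulate.simulate_pointing(exp1_small, "projection_plane", noise=noise8, seed=3)
        f = fit_model(rec, exp1_small, "projection_plane", noise=noise8, n_mode="shots")
        assert f.n_obs == len(rec)
        assert f.n_mode == "shots"

    def test_generator_wins_bic_on_its_own_data(self, exp1_small, noise8):
        """Single-replicate slice of the recovery matrix: the path-integration
        generator (gain 0.8) is identified against all rivals."""
        rec = simulate.participant_cohort(
            exp1_small, 6, "path_integration",
            params={"translation_gain": 0.8, "rotation_gain": 0.9},
            noise=noise8, seed=21,
        )
        fits = [fit_model(rec, exp1_small, mid, noise=noise8, seed=1,
                          retrofit_grid_resolution=0.2)
                for mid in models.MODEL_IDS]
        rep = compare_models(fits, records=rec)
        assert rep.loc[0, "model_id"] == "path_integration"
        assert rep.loc[0, "participant_wins"] == 6
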