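"""Model fitting, scoring, and the study-level statistics.

Units of analysis follow the pointing literature: signed errors are first
reduced to circular (resultant-vector) means per design cell, and models are
scored against those cell means with RMSE, Pearson r and regression slope
(observed on predicted), and information criteria

    AIC = 2k − 2 lnL,     BIC = k ln N − 2 lnL,

where k counts the free parameters actually optimised and N the scoring
units (cell means by default; per-shot scoring is available and always
recorded in the result).  The log-likelihood is Gaussian in the wrapped
residuals with the ML plug-in variance; the variance is profiled identically
for every model and therefore not counted in k.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .geometry import wrap_angle, signed_error
from .models import (
    CELL_KEYS,
    MODEL_IDS,
    CellPredictor,
    RetrofitParams,
    coerce_params,
    retrofit_targets,
)
from .noise import NoiseSpec

__all__ = [
    "PairingError",
    "TTestResult",
    "FitResult",
    "circular_mean",
    "mean_errors_by_cell",
    "condition_correlation",
    "one_sample_t",
    "paired_wall_differences",
    "fit_model",
    "compare_models",
    "participant_bic_wins",
]

log = logging.getLogger(__name__)


class PairingError(ValueError):
    """Trials could not be matched one-to-one across paired conditions."""


def circular_mean(values_deg) -> float:
    """Resultant-vector mean direction in degrees, wrapped to (−180, 180].

    Unlike a scalar average this is well defined across the ±180° cut:
    the mean of {179°, −179°} is 180°, not 0°.
    """
    v = np.radians(np.asarray(values_deg, dtype=float))
    if v.size == 0:
        raise ValueError("circular mean of an empty sample")
    return wrap_angle(math.degrees(math.atan2(np.mean(np.sin(v)), np.mean(np.cos(v)))))


def mean_errors_by_cell(records: pd.DataFrame, keys: list[str] | None = None,
                        value: str = "signed_error_deg") -> pd.DataFrame:
    """Circular-mean signed error per design cell.

    ``keys`` defaults to every design key present in the table (participant,
    run, layout, wall, route, zone, box).  Rows with missing values are
    excluded with a logged warning.
    """
    if keys is None:
        candidates = ["participant_id", "run", "layout_id", "wall", "route",
                      "zone_id", "box_colour"]
        keys = [k for k in candidates if k in records.columns]
    if not keys:
        raise ValueError("no grouping keys available")
    data = records
    n_bad = int(data[value].isna().sum())
    if n_bad:
        log.warning("dropping %d records with missing %s", n_bad, value)
        data = data.dropna(subset=[value])
    if data.empty:
        raise ValueError("no records left to aggregate")
    out = (
        data.groupby(keys, sort=True, observed=True)[value]
        .agg([("mean_error_deg", circular_mean), ("n_shots", "size")])
        .reset_index()
    )
    return out


def condition_correlation(x, y) -> tuple[float, float]:
    """Pearson r and OLS slope of ``y`` on ``x`` (free intercept)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired, equal-length 1-D vectors required")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("slope undefined: no variance in x")
    slope = float(np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1))
    r = float(sps.pearsonr(x, y).statistic)
    return r, slope


@dataclass(frozen=True)
class TTestResult:
    mean: float
    sd: float
    df: int
    t: float
    p: float
    n: int

    def __str__(self):  # printed like the journals print it
        return f"M = {self.mean:.2f}, SD = {self.sd:.2f}, t({self.df}) = {self.t:.2f}, p = {self.p:.3g}"


def one_sample_t(values=None, *, mean: float | None = None, sd: float | None = None,
                 n: int | None = None) -> TTestResult:
    """Two-tailed one-sample t-test against zero.

    Accepts either raw values or the printed summary (M, SD, n); both routes
    use t = M / (SD / √n) with df = n − 1 and agree to numerical precision.
    """
    if values is not None:
        v = np.asarray(values, dtype=float)
        if v.size < 2:
            raise ValueError("need at least two values")
        mean = float(np.mean(v))
        sd = float(np.std(v, ddof=1))
        n = int(v.size)
    if mean is None or sd is None or n is None:
        raise ValueError("give raw values or all of (mean, sd, n)")
    if n < 2:
        raise ValueError("need n >= 2")
    if sd <= 0:
        raise ValueError("degenerate test: SD must be positive")
    t = mean / (sd / math.sqrt(n))
    df = n - 1
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TTestResult(mean=mean, sd=sd, df=df, t=t, p=p, n=n)


def paired_wall_differences(records: pd.DataFrame,
                            pairing_keys: list[str] | None = None,
                            base_wall: str = "EW",
                            reference: str = "ground_truth",
                            predictions: pd.DataFrame | None = None) -> pd.DataFrame:
    """Wrapped error differences between trials paired across wall orientation.

    Trials are matched on ``pairing_keys`` (participant, run, layout, zone,
    box by default) so that the only difference within a pair is the
    orientation of the obscuring wall; shots within a trial are reduced to a
    circular mean first.  With ``reference='model_prediction'`` the errors
    are taken relative to a model's predicted directions (``predictions``
    from :func:`spatialpoint.models.predict_table`) instead of ground truth.

    Returns one row per pair with ``delta_deg`` = (error under the base wall)
    − (error under the paired wall), wrapped.
    """
    if reference not in ("ground_truth", "model_prediction"):
        raise ValueError("reference must be 'ground_truth' or 'model_prediction'")
    data = records.copy()
    if reference == "model_prediction":
        if predictions is None:
            raise ValueError("model-referenced differences need a prediction table")
        data = data.merge(
            predictions[CELL_KEYS + ["predicted_direction_deg"]],
            on=CELL_KEYS, how="left", validate="many_to_one",
        )
        if data["predicted_direction_deg"].isna().any():
            raise ValueError("records contain cells absent from the prediction table")
        data["_err"] = signed_error(data["shot_direction_deg"].to_numpy(),
                                    data["predicted_direction_deg"].to_numpy())
    else:
        data["_err"] = data["signed_error_deg"]

    if pairing_keys is None:
        candidates = ["participant_id", "run", "layout_id", "zone_id", "box_colour"]
        pairing_keys = [k for k in candidates if k in data.columns]
    per_trial = (
        data.groupby(pairing_keys + ["wall"], sort=True, observed=True)["_err"]
        .agg(circular_mean)
        .reset_index()
    )
    wide = per_trial.pivot_table(index=pairing_keys, columns="wall", values="_err",
                                 aggfunc="first")
    offenders = wide.index[wide.notna().sum(axis=1) != 2].tolist()
    if offenders:
        raise PairingError(
            f"{len(offenders)} trial groups lack exactly one partner condition, "
            f"e.g. {offenders[:5]}"
        )
    if base_wall not in wide.columns:
        raise PairingError(f"no trials with base wall {base_wall!r}")
    other_cols = [c for c in wide.columns if c != base_wall]
    out = wide.reset_index()
    base = out[base_wall].to_numpy()
    other = np.full(len(out), np.nan)
    other_label = np.empty(len(out), dtype=object)
    for c in other_cols:
        mask = out[c].notna().to_numpy()
        other[mask] = out.loc[mask, c]
        other_label[mask] = c
    if np.isnan(base).any() or np.isnan(other).any():
        raise PairingError("some pairs lack the base-wall condition")
    result = out[pairing_keys].copy()
    result["wall_base"] = base_wall
    result["wall_other"] = other_label
    result["error_base_deg"] = base
    result["error_other_deg"] = other
    result["delta_deg"] = wrap_angle(base - other)
    return result


# ---------------------------------------------------------------------------
# model fitting and comparison


#: Free parameters and bounds for the directly-optimised models.  The
#: projection-plane model is a zero-parameter rule; retrofit has its own ML
#: routine (2 coordinates per remembered location).
FIT_SPECS: dict[str, tuple[tuple[str, ...], tuple[tuple[float, float], ...]]] = {
    "path_integration": (("translation_gain", "rotation_gain"),
                         ((0.3, 1.7), (0.3, 1.7))),
    "abathic": (("abathic_distance", "compression"),
                ((0.5, 8.0), (0.05, 1.0))),
    "projection_plane": ((), ()),
    "category_mixture": (("w_actual",), ((0.0, 1.0),)),
}


@dataclass
class FitResult:
    """A scored model fit; the AIC/BIC identities hold exactly by construction."""

    model_id: str
    params: object
    k: int
    n_obs: int
    log_likelihood: float
    rmse: float
    pearson_r: float
    slope: float
    aic: float
    bic: float
    converged: bool
    n_mode: str
    noise_family: str
    cell_table: pd.DataFrame = field(repr=False, default=None)

    def summary_row(self) -> dict:
        return {
            "model_id": self.model_id, "k": self.k, "n_obs": self.n_obs,
            "log_likelihood": self.log_likelihood, "rmse": self.rmse,
            "pearson_r": self.pearson_r, "slope": self.slope,
            "aic": self.aic, "bic": self.bic, "converged": self.converged,
        }


def _gaussian_loglik(resid: np.ndarray) -> float:
    n = resid.size
    sigma2 = max(float(np.mean(resid ** 2)), 1e-12)
    return -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)


def _information_criteria(k: int, n: int, lnl: float) -> tuple[float, float]:
    return 2.0 * k - 2.0 * lnl, k * math.log(n) - 2.0 * lnl


def fit_model(records: pd.DataFrame, experiment, model_id: str, *,
              noise: NoiseSpec | None = None, seed: int = 0, n_restarts: int = 5,
              n_mode: str = "cells", fixed_params: dict | None = None,
              retrofit_grid_resolution: float = 0.1,
              predictor: CellPredictor | None = None) -> FitResult:
    """Fit one candidate model to a pointing-record table.

    Parameters are chosen to minimise the RMSE between the per-cell circular
    mean errors and the model's predicted errors, with a bounded
    derivative-free search restarted from ``n_restarts`` seeded points (the
    retrofit model instead maximises its shot likelihood; the
    projection-plane model has nothing to optimise).  Non-convergence is
    flagged on the result, never silent.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model {model_id!r}; have {MODEL_IDS}")
    if n_mode not in ("cells", "shots"):
        raise ValueError("n_mode must be 'cells' or 'shots'")
    if records is None or records.empty:
        raise ValueError("cannot fit to an empty record table")
    noise = noise or NoiseSpec()

    obs = mean_errors_by_cell(records, keys=[k for k in CELL_KEYS if k in records.columns])
    predictor = predictor or CellPredictor(experiment, obs[CELL_KEYS])
    obs_err = obs["mean_error_deg"].to_numpy()

    converged = True
    fixed = dict(fixed_params or {})
    if model_id == "retrofit":
        rf = retrofit_targets(records, experiment, noise=noise,
                              grid_resolution=retrofit_grid_resolution,
                              store_surfaces=False)
        params = RetrofitParams(locations=rf.ml_locations)
        k = rf.n_parameters
    else:
        names, bounds = FIT_SPECS[model_id]
        names = tuple(n for n in names if n not in fixed)
        bounds = tuple(b for n, b in zip(FIT_SPECS[model_id][0], FIT_SPECS[model_id][1])
                       if n not in fixed)
        k = len(names)

        def make_params(x):
            d = dict(zip(names, x))
            d.update(fixed)
            return coerce_params(model_id, d)

        def objective(x):
            resid = wrap_angle(obs_err - predictor.predicted_errors(model_id, make_params(x)))
            return float(np.sqrt(np.mean(resid ** 2)))

        if k == 0:
            params = make_params(())
        else:
            rng = np.random.default_rng(seed)
            defaults = coerce_params(model_id, fixed or None)
            x0s = [np.array([getattr(defaults, n) for n in names], dtype=float)]
            for _ in range(max(0, n_restarts - 1)):
                x0s.append(np.array([rng.uniform(lo, hi) for lo, hi in bounds]))
            best = None
            converged = False
            for x0 in x0s:
                res = optimize.minimize(objective, x0, method="Nelder-Mead", bounds=bounds,
                                        options={"xatol": 1e-6, "fatol": 1e-10,
                                                 "maxiter": 2000})
                converged = converged or bool(res.success)
                if best is None or res.fun < best.fun:
                    best = res
            params = make_params(best.x)
            if not converged:
                log.warning("fit of %s did not converge from any restart", model_id)

    pred_err = predictor.predicted_errors(model_id, params)
    resid = wrap_angle(obs_err - pred_err)
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    try:
        r, slope = condition_correlation(pred_err, obs_err)
    except ValueError:  # e.g. a constant prediction vector
        r, slope = float("nan"), float("nan")

    if n_mode == "cells":
        lnl = _gaussian_loglik(resid)
        n_obs = resid.size
    else:
        shot = records.merge(
            obs[CELL_KEYS].join(pd.Series(pred_err, name="_pred")),
            on=CELL_KEYS, how="left", validate="many_to_one",
        )
        shot_resid = wrap_angle(shot["signed_error_deg"].to_numpy() - shot["_pred"].to_numpy())
        lnl = _gaussian_loglik(shot_resid)
        n_obs = shot_resid.size
    aic, bic = _information_criteria(k, n_obs, lnl)

    cell_table = obs.copy()
    cell_table["predicted_error_deg"] = pred_err
    cell_table["residual_deg"] = resid
    return FitResult(
        model_id=model_id, params=params, k=k, n_obs=n_obs, log_likelihood=lnl,
        rmse=rmse, pearson_r=r, slope=slope, aic=aic, bic=bic, converged=converged,
        n_mode=n_mode, noise_family=noise.family, cell_table=cell_table,
    )


def compare_models(fits: list[FitResult], records: pd.DataFrame | None = None) -> pd.DataFrame:
    """Ranked model-comparison report (sorted by BIC, with Δ columns).

    All fits must have been scored on the same observations.  When the raw
    records are supplied, per-participant BIC win counts are added.
    """
    if not fits:
        raise ValueError("nothing to compare")
    n0, mode0 = fits[0].n_obs, fits[0].n_mode
    for f in fits[1:]:
        if f.n_obs != n0 or f.n_mode != mode0:
            raise ValueError("fits were not scored on the same record set")
    table = pd.DataFrame([f.summary_row() for f in fits])
    table["delta_aic"] = table["aic"] - table["aic"].min()
    table["delta_bic"] = table["bic"] - table["bic"].min()
    if records is not None and "participant_id" in records.columns:
        wins = participant_bic_wins(records, fits)
        table["participant_wins"] = table["model_id"].map(wins).fillna(0).astype(int)
    return table.sort_values("bic", ignore_index=True)


def participant_bic_wins(records: pd.DataFrame, fits: list[FitResult]) -> pd.Series:
    """How many participants each model wins on a per-participant BIC.

    Each participant's cell means are scored against every fitted model's
    (shared) predictions; the winner is the model with the lowest BIC for
    that participant.
    """
    per_p = mean_errors_by_cell(
        records, keys=["participant_id"] + [k for k in CELL_KEYS if k in records.columns]
    )
    winners = []
    for pid, grp in per_p.groupby("participant_id"):
        best_model, best_bic = None, np.inf
        for f in fits:
            merged = grp.merge(
                f.cell_table[CELL_KEYS + ["predicted_error_deg"]],
                on=CELL_KEYS, how="left", validate="many_to_one",
            )
            resid = wrap_angle(merged["mean_error_deg"].to_numpy()
                               - merged["predicted_error_deg"].to_numpy())
            lnl = _gaussian_loglik(resid)
            _, bic = _information_criteria(f.k, resid.size, lnl)
            if bic < best_bic:
                best_model, best_bic = f.model_id, bic
        winners.append(best_model)
    return pd.Series(winners).value_counts()
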