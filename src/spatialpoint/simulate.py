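"""Synthetic pointing datasets.

Shots are generated as *model-predicted direction + independent angular
noise*, which is exactly the statistical structure the evaluation code
assumes.  A cohort adds between-participant heterogeneity by jittering the
generating model's parameters once per participant (never the noise spread,
so cohort-level biases stay interpretable).  Everything is reproducible from
a single integer seed.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .designs import ConfigurationError, Experiment
from .geometry import signed_error, wrap_angle
from .models import (
    CELL_KEYS,
    MODEL_IDS,
    MixtureParams,
    RetrofitParams,
    coerce_params,
    draw_remembered_locations,
    predict_table,
)
from .noise import NoiseSpec

__all__ = [
    "GENERATOR_DEFAULTS",
    "simulate_pointing",
    "participant_cohort",
    "perturb_params",
]

#: Default generating-model parameters used for synthetic study cohorts.
#: Gains below one give the classic undershoot pattern of misintegrated
#: walking; the abathic and mixture values are the package's reference
#: distortion/weighting settings; the projection plane sits at its standard
#: 1.77 m offset.  The retrofit generator draws remembered locations with an
#: isotropic 0.8 m displacement.
GENERATOR_DEFAULTS: dict[str, dict] = {
    "path_integration": {"translation_gain": 0.8, "rotation_gain": 0.9},
    "abathic": {"abathic_distance": 3.0, "compression": 0.6},
    "projection_plane": {},
    "category_mixture": {"w_actual": 0.82},
    "retrofit": {"displacement_sd": 0.8},
}

RECORD_COLUMNS = [
    "participant_id", "experiment_id", "run", "layout_id", "wall", "route",
    "zone_id", "box_colour", "shot_index",
    "true_direction_deg", "shot_direction_deg", "signed_error_deg",
]


def generator_params(experiment: Experiment, model_id: str, rng: np.random.Generator,
                     overrides: dict | None = None):
    """Materialise default generator parameters for a model.

    The retrofit generator is special: its ``displacement_sd`` is turned into
    a concrete remembered-location set drawn with ``rng``.
    """
    if model_id not in MODEL_IDS:
        raise ConfigurationError(f"unknown generator {model_id!r}; have {MODEL_IDS}")
    spec = dict(GENERATOR_DEFAULTS[model_id])
    spec.update(overrides or {})
    if model_id == "retrofit" and "locations" not in spec:
        sd = spec.pop("displacement_sd")
        spec = {"locations": draw_remembered_locations(experiment, sd, rng)}
    return coerce_params(model_id, spec)


def simulate_pointing(experiment: Experiment, model_id: str, params=None,
                      noise: NoiseSpec | None = NoiseSpec(), seed: int = 0,
                      participant_id: str = "p01") -> pd.DataFrame:
    """One participant's pointing records for a full trial schedule.

    ``noise=None`` produces noiseless shots (every signed error equals the
    generating model's predicted bias exactly).  Byte-identical output for a
    fixed seed.
    """
    params = coerce_params(model_id, params)
    pred = predict_table(experiment, model_id, params)
    rows = experiment.design.rows.merge(pred, on=CELL_KEYS, how="left", validate="many_to_one")
    if rows["predicted_direction_deg"].isna().any():
        raise ConfigurationError("design rows without a model prediction (unknown cell)")

    if noise is None:
        shot = rows["predicted_direction_deg"].to_numpy()
    else:
        rng = np.random.default_rng(seed)
        shot = wrap_angle(rows["predicted_direction_deg"].to_numpy()
                          + noise.draw(rng, len(rows)))
    out = rows.copy()
    out["participant_id"] = participant_id
    out["experiment_id"] = experiment.experiment_id
    out["shot_direction_deg"] = shot
    out["signed_error_deg"] = signed_error(shot, out["true_direction_deg"].to_numpy())
    cols = [c for c in RECORD_COLUMNS if c in out.columns]
    extra = [c for c in ("facing",) if c in out.columns]
    return out[cols[:9] + extra + cols[9:]] if extra else out[cols]


def perturb_params(model_id: str, params, spread: float, rng: np.random.Generator):
    """Per-participant jitter of a generating model's parameters.

    ``spread`` is a fractional/log-scale amount for the strictly positive
    parameters (gains, abathic distance, plane offset), an additive amount
    for the mixture weight (clipped to [0.01, 1]), and metres of additional
    location scatter for the retrofit generator.  ``spread = 0`` returns the
    parameters unchanged.
    """
    if spread < 0:
        raise ConfigurationError("between-participant spread must be >= 0")
    params = coerce_params(model_id, params)
    if spread == 0:
        return params
    if model_id == "path_integration":
        return replace(
            params,
            translation_gain=params.translation_gain * float(np.exp(rng.normal(0, spread))),
            rotation_gain=params.rotation_gain * float(np.exp(rng.normal(0, spread))),
        )
    if model_id == "abathic":
        return replace(
            params,
            abathic_distance=params.abathic_distance * float(np.exp(rng.normal(0, spread))),
            compression=float(np.clip(params.compression * np.exp(rng.normal(0, spread)),
                                      0.05, 1.0)),
        )
    if model_id == "projection_plane":
        return replace(params,
                       plane_offset=params.plane_offset * float(np.exp(rng.normal(0, spread))))
    if model_id == "category_mixture":
        return MixtureParams(
            w_actual=float(np.clip(params.w_actual + rng.normal(0, spread), 0.01, 1.0)),
            alternative_zone=params.alternative_zone,
        )
    # retrofit: extra independent scatter of the remembered locations
    locs = {k: tuple(np.asarray(v, dtype=float) + rng.normal(0, spread, size=2))
            for k, v in params.locations.items()}
    return RetrofitParams(locations=locs)


def participant_cohort(experiment: Experiment, n_participants: int, model_id: str,
                       params=None, noise: NoiseSpec | None = NoiseSpec(),
                       between_participant_sd: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Simulate a cohort: one parameter draw per participant, then shots.

    With ``between_participant_sd = 0`` every participant shares the base
    generator's expected biases.
    """
    if n_participants < 1:
        raise ConfigurationError("need at least one participant")
    ss = np.random.SeedSequence(seed)
    param_rng = np.random.default_rng(ss.spawn(1)[0])
    base = generator_params(experiment, model_id, param_rng) if params is None \
        else coerce_params(model_id, params)
    shot_seeds = [int(s) & 0x7FFFFFFF for s in ss.generate_state(n_participants)]
    frames = []
    for i in range(n_participants):
        p_params = perturb_params(model_id, base, between_participant_sd, param_rng)
        frames.append(simulate_pointing(
            experiment, model_id, p_params, noise=noise, seed=shot_seeds[i],
            participant_id=f"p{i + 1:02d}",
        ))
    return pd.concat(frames, ignore_index=True)
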