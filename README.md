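# spatialpoint

Modelling pointing biases in spatial-updating experiments, in 2-D plan view.

In the task this package models, an observer studies four coloured target
boxes from a start zone, walks behind a partition to a pointing zone, and
then repeatedly "shoots" at each box from memory. People are strikingly
biased at this: signed pointing errors (shot bearing minus true target
bearing, anticlockwise positive) of tens of degrees that are highly
repeatable across routes, facing directions and participants, flip sign with
the side of the pointing zone, and — critically — change with the
orientation of the wall that hides the targets. `spatialpoint` is for
researchers who want to simulate such experiments, generate synthetic
pointing datasets with known structure, and compare candidate models of the
bias on synthetic or real data.

## The candidate models

Each model maps (scene, pointing zone, target box) → predicted pointing
bearing; predicted signed error is the wrapped difference from the true
bearing:

* **Noisy path integration** — the scene is remembered correctly but each
  turn and step of the walked path is misintegrated (believed turn =
  `rotation_gain` × turn, believed step = `translation_gain` × step); the
  observer aims from the believed position and executes relative to the
  believed heading. Predicts route-dependent errors.
* **Abathic-distance distortion** — encoding compresses radial distance
  about the start zone, d′ = a + c(d − a): correct at the abathic distance
  *a*, compressed toward it elsewhere (c ∈ (0, 1]).
* **Retrofit** — inverse inference: one remembered location per (layout,
  box), 2 free coordinates each, chosen by maximum likelihood so that a
  single location set explains the shots from *all* zones and wall
  conditions.
* **Projection plane** — a zero-parameter rule: remembered targets lie on a
  plane parallel to, and 1.77 m behind, the central obscuring wall, placed
  along the sight-line from the start zone. The prediction falls between the
  true target direction and the wall normal, so it is the only candidate
  whose predictions depend on wall orientation.
* **Category mixture** — a resultant-vector circular mean of the target's
  direction from the actual zone (weight 0.82) and from an alternative zone
  (weight 0.18).

Models are scored on per-cell circular-mean errors with RMSE, Pearson r and
slope (observed on predicted), and AIC/BIC (`AIC = 2k − 2 lnL`,
`BIC = k ln N − 2 lnL`); paired wall-orientation differences and one-sample
t-tests reproduce the field's standard summaries. See `docs/methods.md` for
the full definitions and numerical choices.

## Worked example

Simulate a 10-participant cohort on the paired-wall design (`exp4`: same
start zone, pointing zone and box layout tested under two wall orientations)
with the projection-plane generator and 8° shot noise, then compare all five
models:

```bash
$ spatialpoint simulate --preset exp4 --generator projection_plane \
      --n-participants 10 --noise-sd 8 --seed 7 --out run
wrote 15360 records to run/records.csv

$ spatialpoint compare --records run/records.csv --preset exp4 --out cmp
        model_id  k  n_obs     rmse  pearson_r    slope        bic  delta_bic  participant_wins
projection_plane  0    128 0.685611   0.999080 1.001664 266.622491   0.000000                10
         abathic  2    128 5.223191   0.944833 1.004987 796.148086 529.525596                 0
path_integration  2    128 5.686563   0.934322 1.013295 817.907450 551.284960                 0
category_mixture  1    128 7.798809   0.872449 0.981706 893.916882 627.294391                 0
        retrofit 32    128 4.655570   0.956461 0.990882 912.257680 645.635189                 0
```

(Columns abridged.) Reading the report: the zero-parameter projection-plane
rule reproduces its own data to 0.7° RMSE across the 128 design cells and
wins the BIC for all 10 participants; the point-distortion models (abathic,
retrofit) cannot follow the wall-orientation dependence, so they are
hundreds of BIC points behind despite their free parameters — the retrofit's
32 location coordinates buy accuracy (RMSE 4.7°) but not enough likelihood
to offset the `k ln N` penalty. `cmp/paired_wall_differences.csv` holds the
per-pair wrapped error differences (e.g. participant p01, zone B, blue box:
+6.6° between the East-West and slanted-wall conditions), and every output
directory contains a `manifest.json` with the config, seeds and file
checksums needed to reproduce it byte for byte.

The same machinery is available as a library:

```python
import spatialpoint as sp

exp = sp.make_experiment("exp1", n_layouts=4)
records = sp.participant_cohort(exp, 20, "projection_plane",
                                noise=sp.NoiseSpec(sd_deg=8.0), seed=1)
fit = sp.fit_model(records, exp, "abathic")
print(fit.rmse, fit.bic, fit.params)
```

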