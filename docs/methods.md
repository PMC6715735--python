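# Methods

`spatialpoint` models a spatial-updating pointing task: an observer studies
four coloured target boxes from a start zone, walks behind a partition to a
pointing zone, and "shoots" repeatedly at each remembered box. The analysis
is entirely planar. This note records the model definitions, the geometry of
the bundled designs, the synthetic-data assumptions, the scoring rules, and
the numerical choices, so that every number the package produces can be
traced to a stated decision.

## Coordinate and angle conventions

Positions are metres in plan view (x East, y North). Directions are bearings
in degrees, anticlockwise from due East, wrapped to the half-open interval
(−180, 180] so that each direction has one representative and signed errors
are symmetric about zero. The signed pointing error is the wrapped
difference `shot − true`; positive means the shot was anticlockwise of the
true target direction. Points closer than 1e-9 m are treated as coincident
and raise degenerate-geometry errors rather than returning noise.

Wall height and eye height never enter any computation; walls matter only
through the position and orientation of their infinite 2-D line.

## The bundled designs

All presets share one canonical room (6 m × 6 m, coordinates in
`designs.py`): the start zone at (0, −2.2) faces North; the four boxes lie
on two visual lines through the start zone, 25° apart, bisected by the
facing direction, with the blue box nearer than the pink on one line and the
red nearer than the yellow on the other. Box distances are sampled per
layout — near boxes from 1.8–2.2 m, far boxes from 2.4–2.8 m — and an
independent validator re-checks the collinearity, the 25° separation, the
depth ordering and the room bounds on every generated scene. The central
obscuring wall's line passes 1.2 m in front of the start zone, between the
observer region and the boxes; with the standard 1.77 m projection-plane
offset this places every box between the wall and the plane. Published
coordinates of the original layouts are not included; externally supplied
scenes can be loaded from YAML instead.

Pointing zones sit behind the wall: A and B west of the target fan, C east
of it (so the two sides of the fan are represented, which is what makes the
opposite-sign bias pattern appear). The paired-wall preset (`exp4`) uses
zones B, C (west) and their mirror images D, E (east); western zones are
tested under the East-West and the North-West slanted wall, eastern zones
under the East-West and the North-East slanted wall, every other factor held
fixed — 8 conditions × 4 layouts × 4 boxes × 6 shots × 2 runs = 1,536 shots
per participant. The direct/indirect preset (`exp1`) enumerates 1,440 shots
(9 layouts) or 640 (4 layouts); `exp2` adds a poster-facing factor as pure
bookkeeping; `exp3` scales the room by 1.5 in the plane and mirrors zones
A–C into D–F across the room's centre line.

Walking routes are polylines. Indirect routes detour around the inner
partition (the detour for zone C is roughly three times the direct path);
designs whose walls appear only after the participant leaves the start zone
use straight routes. Routes matter only to the path-integration model.

## The five candidate models

Each model maps (scene, zone, box) to a predicted pointing bearing. All
reduce to the true direction in their veridical limits, which the tests
assert to 1e-9° (floating-point round-off on chained trigonometry; the
retrofit limit, being an optimiser output, is held to its grid/refinement
scale instead).

**Noisy path integration** (`translation_gain`, `rotation_gain`). The scene
is remembered correctly but self-motion is misintegrated: every turn is
scaled by the rotation gain and every step by the translation gain, giving a
believed position and heading at the end of the walked path. The observer
aims at the true box from the believed position and executes the direction
relative to their believed heading, so the residual heading error
(actual − believed) is added to the intended bearing. Gains are systematic,
so the model predicts mean errors; predicted biases grow with path length,
and direct versus indirect routes to the same zone produce different
predictions — the model's signature. A stochastic per-step variant is not
implemented; the comparison operates on mean errors throughout.

**Abathic-distance distortion** (`abathic_distance` a, `compression` c).
Encoding from the start zone distorts radial distance: d′ = a + c(d − a),
correct at the abathic distance and compressed toward it elsewhere
(implemented as d′ = c·d + (1−c)·a so c = 1 is an exact fixed point in
floating point). The remembered box keeps its visual direction from the
start zone; the prediction is the bearing from the zone to the remembered
box. Defaults a = 3 m, c = 0.6.

**Retrofit** (2 coordinates per remembered location). Inverse inference:
one remembered location per (layout, box) maximises the summed log-density
of the angular deviations between every shot and the bearing from that
shot's zone to the candidate location — the same location must explain all
zones and all wall conditions. The likelihood family and spread come from
the declared noise specification (the spread is fixed, not fitted, and does
not count toward the parameter total). Optimisation is a coarse grid scan
(default 0.1 m over the room plus a 1 m margin; ties broken deterministically
toward the grid centroid) followed by Nelder–Mead refinement. The grid
argmax and the refined peak agree to within one grid cell; a
double-resolution brute-force scan is used as the oracle in tests. At least
two distinct zones per box are required, otherwise the location is
unidentifiable and the fit refuses to run.

**Projection plane** (zero free parameters). Remembered targets all lie on a
line parallel to the central obscuring wall, offset 1.77 m on the target
side, placed along the sight-line from the start-zone centre (projection is
along the encoding viewpoint's ray, not orthogonal; an orthogonal variant is
available as a labelled alternative for sensitivity analysis). The
prediction is the bearing from the zone to the projected box. With targets
between the wall and the plane, the remembered target is pushed outward and
the predicted direction falls between the true target bearing and the
wall-normal bearing — provided the zone is laterally clear of the projected
sight-line fan and lies between the start zone's depth and the wall, as the
pointing zones in these rooms always do. That betweenness is checked over
1,000 randomised scenes drawn from exactly that geometry family. It is not
asserted for slanted-wall conditions with zones near the slanted normal,
where it genuinely need not hold.

**Category mixture** (`w_actual`). The response is the resultant-vector
circular mean of the target's true direction from the actual zone (weight
w, default 0.82) and its direction from an alternative zone (weight 1 − w).
Scalar averaging of wrapped angles is ill-defined across the ±180° cut,
hence the vector mean; antipodal directions with equal weights raise an
explicit error. When no alternative zone is named, an opposite-side rule
picks the laterally nearest zone on the other side of the sight axis (at
zone C the rule selects zone B in the canonical room), falling back to the
laterally most distant zone when all zones share a side.

## Synthetic data

Shots are `model prediction + independent angular noise`, i.i.d. within a
cell — the package makes no claim about serial dependence, learning across
trials, or first-trial effects, and real data may violate all three.
Passing tests therefore certify the pipeline's internal consistency, not
that any of the five models describes human pointing.

The default noise family is a wrapped Gaussian with σ = 8°, the order of
within-cell spread compatible with published condition-level SDs around 20°
once between-condition structure is included; von Mises (κ matched as
1/σ²) is the labelled alternative, and the family used is recorded in every
result. The wrapped-Gaussian log-density keeps only the nearest wrap image,
accurate to better than 1e-6 for spreads up to ~30°.

Cohorts draw one parameter perturbation per participant (log-scale spread
for strictly positive parameters, additive for the mixture weight, metres of
scatter for remembered locations) and never perturb the noise spread, so
cohort-level mean biases stay interpretable; a spread of zero reproduces the
degenerate identical-participant cohort exactly. Everything is reproducible
from one integer seed via spawned child seeds.

## Fitting and scoring

Signed errors are reduced to resultant-vector circular means per design cell
(layout × wall × route × zone × box), matching the condition-mean unit of
analysis used in this literature. Models are fitted by minimising the RMSE
between observed cell means and predicted errors with bounded Nelder–Mead
from 5 seeded restarts (parameter spaces are 0–2 dimensional; retrofit has
its own ML routine). Non-convergence is flagged on the result, never
silent.

Scoring: RMSE; Pearson r and the OLS slope of observed on predicted errors
(regression direction recorded — total least squares is not implemented);
and information criteria AIC = 2k − 2 lnL, BIC = k ln N − 2 lnL with a
Gaussian likelihood in the wrapped residuals using the ML plug-in variance.
The variance is profiled identically for every model and not counted in k.
N counts cell means by default; a per-shot mode exists and is recorded in
the result (`n_mode`) since the choice changes the BIC penalty materially.
Per-participant win counts score each participant's own cell means against
the shared fitted predictions.

Paired wall-orientation differences match trials on participant, run,
layout, zone and box, reduce shots to a circular mean per trial, and take
the wrapped difference of the base-wall condition minus its partner, either
against ground truth or against a model's predictions; unmatched trials are
an error that names the offenders. One-sample t-tests are two-tailed,
computed identically from raw values or from printed (M, SD, n) summaries;
no multiple-testing correction is applied, matching how such tests are
conventionally reported.

## Self-consistency results the package certifies

The `validation` module (used by both the test suite and
`scripts/acceptance.py`) recomputes, from scratch: a BIC model-recovery
matrix (each of the five generators recovered as the winner on its own
synthetic cohorts — 20 replicates of 6-participant cohorts on the 4-layout
direct/indirect design at σ = 8°, retrofit grid 0.2 m, sizes chosen to keep
the full matrix near two minutes of CPU); retrofit location recovery (3
zones × 8 shots at σ = 8°, 100 replicates, 90th-percentile location error
below 0.3 m); the projection-plane betweenness property over 1,000
randomised scenes; and the paired-wall structure on projection-plane
generated cohorts (differences against ground truth significantly nonzero
with mirrored signs at the mirrored zones; differences against the
generating model's own predictions centred on zero — the structural analogue
of a wall effect that the model fully absorbs).

One caveat worth knowing when interpreting comparisons on single-wall
designs: with only one wall orientation, the abathic model can imitate the
projection rule almost perfectly (the projection sends every box to a nearly
constant distance from the start zone, which is the c → 0 abathic limit), and
at large cohort sizes with heterogeneous participants it can edge ahead of
the fixed-offset zero-parameter rule by a few BIC points. The wall-
orientation manipulation is what separates the model families; headline
comparisons should therefore use the paired-wall design, as the acceptance
script does.

## Known limitations

Strictly 2-D; no stochastic path-integration variance predictions; no
binocular/cyclopean ray construction; the bundled layouts are a constraint-
faithful stand-in for the unpublished originals, so numerical values of
fits to real data will differ from any published table even though the
structural behaviour is preserved; shot order effects, reaction times and
kinematics are out of scope.
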