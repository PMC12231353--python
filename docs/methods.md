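# Methods

This note documents the models, parameters and numerical choices behind
`screwscape`, and what the synthetic pipeline does and does not demonstrate
about real plate/bone systems.

## Screw geometry

Each of the seven proximal screws (ids 6–12; Screw 6 is the inferior-medial
calcar screw) is a **capsule**: the segment from the fixed head point to the
tip, swept by the screw radius (default 1.5 mm, i.e. a 3 mm cylinder).
Coordinates are right-handed millimetres with x = anterior, y = proximal,
z = lateral.

**Tilt composition.** A screw's orientation state is a pair of grid angles
(dp, ap).  The tilted direction is

    d(dp, ap) = normalize(n + tan(dp)·u_dp + tan(ap)·u_ap)

where (n, u_dp, u_ap) is the anchor's orthonormal frame.  Single-axis tilts
are then exact rotations by the stated angle, the two axes commute, and
d(−dp, −ap) mirrors d(dp, ap) about the neutral axis.  How simultaneous
tilts should compose is genuinely open (any choice agreeing on single-axis
tilts is defensible); the tangent-offset form was chosen for its symmetry
and because it matches the "tip moves on a grid" picture of a variable-angle
locking screw.

**Length under the TJD constraint.** The glenohumeral joint surface is
modelled as a sphere — the humeral head is near-spherical and the
constraint only needs a closed surface with a ray intersection.  The screw
length is t* − TJD, where t* is the far root of the ray–sphere quadratic
from the head along d.  A ray that misses the sphere, or a length that
comes out non-positive, raises a geometry error tagged with the screw id.
TJD defaults to 8 mm.

**Collision.** Two screws collide when the minimum distance between their
closed axis segments is *strictly* below the sum of their radii.  The
distance is the standard closed-form closest-point computation with clamped
parameters (degenerate and parallel segments handled explicitly).  Strict
inequality is a deliberate tie-break: grazing contact is numerically
unstable under any rule, and a fixed convention keeps the labelling
deterministic.  Capsules rather than flat-capped cylinders were chosen
because the contact test then reduces to a segment distance; the two models
differ only on a measure-zero set of configurations.

**Default fixture.** The real plate geometry that motivated this pipeline
is proprietary, so the package ships a documented synthetic fixture: a
24 mm joint sphere at the origin, heads on the lateral plate surface
(z ≈ 28–29 mm), and neutral axes aimed at targets scaled to ~0.78× the
head footprint, i.e. a nearly parallel, slightly convergent fan.  The
neutral configuration clears by ≈ 4.2 mm, converging neighbour tilts (e.g.
screws 7/8 at ∓10° toward each other) collide, and roughly four of five
random grid configurations collide — the attrition regime a tightly
clustered seven-screw cluster produces, and the regime the emulated study
design operates in.  All geometry-dependent numbers in this package are
fixture-relative; none are claimed to match any particular implant.

On a discrete grid each screw's pose depends only on its own state, so each
pair of screws has an (L²×L²) collision table; labelling a batch of N
configurations is then 21 table lookups per row.  This exact vectorized path
is what makes full-factorial truth labelling (4 782 969 rows) cheap.

## Synthetic strain oracle

The oracle replaces the FE solver.  It reports magnitudes (positive
μstrain) of the compressive (minimum principal) strain percentiles —
ε₅₀ and ε₉₀ — around each screw and pooled over all screws, as a
deterministic surface plus optional noise:

    log ε₅₀,s = log(baseline_s)
              + Σ_k gain_k · (c₁·dp_k + c₂·dp_k² + c₃·ap_k + c₄·ap_k²)
              + collision_inflation · flag
              − q · log(E_s / E_ref)

with ε₉₀,s = γ_s · ε₅₀,s (γ_s > 1), gain_k = `calcar_gain` for the calcar
screw and 1 otherwise, and E_s the Morgan modulus `6850·ρ_app^1.49` of the
bone around screw s (q = `modulus_scale_exponent`, default 1: locally
softer bone strains proportionally more; E_ref is the modulus at the
reference density so the default density field is neutral).

The log-additive quadratic form is not claimed to be mechanically derived;
it is the simplest smooth surface that embeds the qualitative structure an
FE study of this system reports — calcar dominance, proximal tilt
beneficial, distal tilt harmful, smooth curvature across the ±10° range —
while staying cheap enough to evaluate exhaustively.

**Pooled percentiles.** "All screws" values are quantiles of a declared
synthetic element population: an equal-weight mixture of per-screw
lognormals with median ε₅₀,s and 90th percentile ε₉₀,s (log-sd
σ_s = ln γ_s / z₀.₉).  Whether a real post-processor would pool raw element
strains or aggregate per-screw percentiles is unknowable from outside; the
mixture is a convention, stated here, not an inference.  The mixture
quantile is solved in log space by bracketed safeguarded Newton iteration
(vectorized over rows, terminating at step < 1e-12, ~1e-12 relative
accuracy, fully deterministic).

**Calibration of defaults.** At construction, `default_params()` solves for
the calcar screw's dp coefficients so that tilting *only* Screw 6 by −10°
(distal) multiplies its own ε₅₀ by 1.4506 and the pooled ε₉₀ by 1.3645, and
by +10° by 0.7751 and 0.8722 respectively (own-strain coefficients in
closed form; pooled coefficients by a 2-D root solve through the mixture
quantile).  Every other screw reuses the same base coefficients divided by
`calcar_gain` (default 3), so the calcar screw's marginal log-effect
exceeds every other screw's by exactly that factor.  Anterior–posterior
coefficients are fixed modest values (anterior tilt mildly beneficial) and
are not calibrated.

**Collisions and noise.** The oracle emits strain for colliding
configurations too, inflated by `collision_inflation` (default 0.15 in log
space, ≈ +16%).  An FE campaign would simply lose those runs — its
colliding models fail — which would make a collision *input* feature
constant on surviving training rows; emitting inflated strain instead keeps
the 16-input regressor's collision feature informative and makes the
16-vs-14-input comparison meaningful.  This is a deliberate divergence from
what a physical pipeline could observe.  Noise is multiplicative lognormal
with **unit median** (not unit mean) and coefficient of variation
`noise_cv` (default 0.02), one shared factor per (ε₅₀, ε₉₀) key pair so the
percentile ordering survives draw by draw.  Factors come from a
counter-based stream keyed by (seed, draw_index), making records
reproducible and independent of generation order.

## Designs

Training designs are Latin Hypercube draws in [0,1)¹⁴ snapped to grid
levels by equal-probability binning (preserving marginal stratification on
a discrete grid), with exact duplicate rows replaced by fresh draws (cap:
100·n total).  The 7500-point design is the concatenation of the 500/2000/
5000 designs, not a fresh draw.  Splits are 80/10/10 with round(n·f) rows
in validation and test and the remainder in training (1341 → 1073/134/134).
The reduced full factorial (levels {−10, 0, +10}°, 9⁷ = 4 782 969 rows) is
enumerated lexicographically in bounded batches via linear-index unraveling.

## Surrogate networks and trainers

Architectures: collision classifier [14, 25, 1]; strain regressors
[16, 10, 5, 1] (angles + collision) and [14, 10, 5, 1] (angles only).
Hidden activations are tanh and the output layer is linear — the standard
companions of the trainers used; the classifier thresholds its raw linear
output at 0.5 against {0, 1} targets.  The stated 16-input count is met by
one-hot encoding the collision information as two complementary indicators
(collision, no-collision) next to the 14 angles.  At training time the flag
is the dataset's true label; at prediction time it is the collision
classifier's output, so the deployed pair composes exactly as the study
design describes.  Inputs (and regressor targets) are min–max scaled to
[−1, 1], fitted on training rows only and stored with the model.

**Initialization** is Nguyen–Widrow-style for hidden layers (random
directions scaled to 0.7·h^(1/n), biases spread over the active region) and
small uniform for the output layer, reproducible from a seed.

**Levenberg–Marquardt.** Each epoch builds the exact per-sample Jacobian of
the scalar output by backpropagation and takes the damped Gauss–Newton step
Δw = (JᵀJ + μI)⁻¹Jᵀe, retrying with μ ← 10μ until the SSE drops and
relaxing μ ← 0.1μ on acceptance (μ₀ = 1e-3, overflow cap 1e10).  Stopping:
max_epochs (default 1000; 150 in the study-scale runs), gradient ∞-norm
below 1e-7, μ overflow, or six consecutive validation-SSE increases with
restoration of the best-validation weights.  The Jacobian is verified
against central finite differences in the test suite.

**Bayesian regularization.** LM steps on F = β·E_D + α·E_W (E_D = Σe²,
E_W = Σw²) with MacKay evidence updates after each accepted step:
γ = N_w − 2α·tr(H⁻¹) with H = 2βJᵀJ + 2αI, then α = γ/(2E_W),
β = (N − γ)/(2E_D), starting from α = 0, β = 1.  γ is additionally clamped
to min(N_w, N − 1): the number of well-determined parameters can exceed
neither the weight count nor the data count, and the clamp keeps β positive
when the network is larger than the sample.  Validation rows are folded
into training (the trainer regularizes instead of early-stopping).
Training stops when α, β, γ are stable to 1e-4 for three epochs, or at
max_epochs.

**Replicates and selection.** Robustness ensembles retrain from distinct
initialization seeds (derived from one base seed) on the same split; the
reported model is the replicate with the best metric (accuracy / RMSE) on
the designated evaluation table, ties breaking to the lowest replicate
index, and summaries report best alongside the replicate mean.  Selecting
on the external test set mirrors the emulated study's reporting and
carries the usual optimistic-selection bias — the headline "best" accuracy
of a classifier whose true generalization sits near the collision base
rate is inflated by a few points, which is precisely the regime the
original tables exhibit.

## Statistics

* R² = 1 − SS_res/SS_tot with residuals (pred − true); slope is the OLS
  slope of pred on true with intercept.  "% RMSE" is not a standard
  quantity; here it is 100·RMSE/(max − min of the observed test values), a
  convention consistent with the constant μstrain↔% ratios within a
  reported column.
* All two-sample tests are Welch (unequal variances), two-sided, with
  Satterthwaite degrees of freedom — group sizes in the heatmap differ
  wildly, making the pooled-variance t inappropriate.  No multiple-testing
  correction is applied; thresholds (0.001 for heatmap cells, 0.05 for
  range comparisons) are arguments, not constants.
* Full-factorial heatmaps stream in bounded memory: per (screw, tip-state)
  group, exact count/sum/sum-of-squares accumulators over the non-colliding
  predictions.  Welch's statistic needs only count/mean/variance, so the
  streamed test is *exact* — no subsampling is required or used — and the
  streamed means agree with full materialization.  Cell value:
  100·(mean_state − mean_neutral)/mean_neutral; the neutral cell is 0 with
  p = 1 by construction; empty groups are flagged invalid.  Group means
  (not medians) are the default central tendency; the aggregation across
  configurations is a convention (a median option exists on the CLI
  output tables via the quartile columns of the range comparison).

## Problem sizes used

Study-scale runs in the test suite and acceptance script use the pooled
successful-simulation count of the emulated design: 1341 training rows,
91-row unseen test designs, best-of-20 replicate ensembles (best-of-3 in
the 20-seed dominance sweep), 150-epoch caps, and the full 9⁷ factorial for
every heatmap.  These sizes were chosen as the smallest that exercise every
stage at the study's own row counts while keeping a laptop-class run in
minutes; the pipeline defaults (500/2000/5000 designs, 100 replicates)
reproduce the full protocol when wanted.

## What passing tests do and do not show

The oracle is smooth, low-order, and exactly log-additive per source screw;
real FE strain fields have mesh noise, contact nonlinearity, density
heterogeneity and inter-subject variation that no desk-scale surrogate of
this kind captures.  Passing recovery tests therefore demonstrates that the
*pipeline* — geometry, designs, trainers, selection, statistics — is
correct and well-conditioned, not that a [16,10,5,1] network would achieve
R² ≈ 0.99 on any particular patient's FE data.  Likewise the collision
classifier's ceiling is a property of this fixture's pair geometry;
fixtures with rarer, sharper collision modes are genuinely harder to learn
from ~1000 rows, and accuracy then tracks the base rate more closely.

## Known limitations

* The joint surface is a sphere and the bone is represented only through a
  per-screw apparent density; there is no mesh, load case, or fracture
  model.
* The oracle has no screw-length sensitivity beyond the TJD constraint and
  no pairwise interaction terms between source screws.
* Best-model selection on the test set inflates headline metrics (kept
  deliberately, to mirror the emulated reporting; the replicate mean is
  always reported alongside).
* LM training cost scales as O(N·P²) per epoch; the [14, 25, 1] classifier
  (P = 401) is near the practical ceiling for this implementation.
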