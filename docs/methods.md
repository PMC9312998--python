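# Methods

This note records the models, numerical choices, and limitations behind
fibmorph, in the order data flow through the pipeline.

## Landmark template and data model

A template is an ordered list of labelled points with a role (fixed
landmark, curve semilandmark, surface semilandmark) and a region
(proximal or distal epiphysis), plus ordered curve sequences (anchored on
fixed endpoint landmarks) and named surface patches. Labels are opaque
strings — the anatomical fibula template's fixed landmarks skip two
numeric labels, so nothing may assume contiguity. Coordinates are
millimetres, (x, y, z), left-side bones only; configurations with missing
or non-finite landmarks are rejected outright (imputation of missing
landmarks is out of scope — the method targets intact epiphyses).

Interchange formats: classic TPS landmark files (`LM3=K` blocks with
`ID=` records) and UTF-8 delimited tables (wide `x1..zK` or long
`specimen_id,label,x,y,z`), with metadata as
`specimen_id,sex,population,age,side`. Round-trips preserve coordinates
to ≤1e−9 mm (files carry 9 decimals).

## Thin-plate splines and bending energy

The 3D interpolating spline uses the radial kernel U(r) = −r plus an
affine term, solved from the bordered system
`[[U, P], [Pᵀ, 0]] [W; A] = [target; 0]` with P = [1 | x | y | z]. The
sign was fixed by requiring the bending-energy matrix — the upper-left
K×K block of the inverse bordered matrix — to be positive semidefinite;
with U(r) = +r it is negative semidefinite. Degenerate references
(coincident or coplanar control points, K < 4) are rejected; a genuine
numerical singularity adds a logged ridge of 1e−10·|trace|. Energies
below 1e−12 clamp to zero so affine-invariance checks are stable.

What is and is not invariant: E is zero exactly on affine deformations,
and unchanged by adding affine functions of the reference to the deformed
configuration or by rotating it. It is **not** invariant under arbitrary
affine post-composition (that rescales the quadratic form), a point
sometimes stated loosely in the sliding literature.

## Sliding semilandmarks

Tangent directions are estimated from coordinates alone, since the
pipeline receives landmarks rather than meshes: curve points take the
central difference of their curve-ordered neighbours (one-sided at
sequence ends); surface points take the two leading principal directions
of their k nearest within-patch neighbours (k = 8 by default; patches
need ≥3 points). Relaxation is a closed-form generalized least squares
step: with T the 3K×q tangent basis and B₃ the per-axis block-diagonal
bending-energy matrix, sliding amplitudes are
t = −(TᵀB₃T)⁻¹ TᵀB₃ y — the projection of the bending-energy gradient
onto the tangent subspace. Fixed landmarks never move.

Because no underlying surface exists to reproject onto, displacements are
capped at twice the median nearest-neighbour spacing per pass, by uniform
scaling — the objective is a convex quadratic minimized at the full step,
so any partial step still decreases energy.

Sample-wide sliding loops {GPA consensus → map consensus into each
specimen's own frame (rotate + rescale + translate) → re-estimate tangent
frames → relax} for 3 outer iterations by default, stopping early when
the largest displacement falls below 1e−4 of the mean centroid size.
Relaxing in specimen space keeps fixed landmarks bit-identical. The total
bending energy to the consensus is tracked per iteration; if a consensus
update raises it (beyond a 1e−6 relative tolerance, which signals
convergence noise rather than descent), iteration stops and the best
iterate is returned — a substantive rise additionally warns. Whether the
original workflow minimized bending energy or Procrustes distance in the
consensus phase is not documented; bending energy is used for both
phases, keeping one auditable criterion.

## Procrustes superimposition

Partial Procrustes GPA: centre, scale to unit centroid size, rotate to
the running consensus by constrained orthogonal Procrustes (SVD with
det +1 enforced — reflections are disallowed because all specimens are
left bones; a reflection-optimal fold flips the smallest singular
direction). Iteration stops when the consensus moves <1e−10 (max 100).
Centroid sizes are recorded in mm before scaling. To make outputs
byte-reproducible across runs, the final consensus (and all aligned
shapes with it) is rotated so its principal axes align with +x, +y, +z
with positive third moments, keeping det +1 by conceding the sign of the
axis with the smallest skew when necessary.

## Ordination

PCA is computed by SVD of the centred data matrix (never by assembling a
covariance matrix), retaining min(N−1, D) components. Form space appends
one unweighted ln CS column. Axis signs follow two conventions: every
axis is oriented so its largest-magnitude loading is positive, and form
PC1 so its ln CS loading is positive — on size-dimorphic samples the
larger sex then plots at positive form PC1 scores.

## Inference

* **Procrustes ANOVA (RRPP).** One-way sums of squares in the flattened
  coordinate space; F = (SSE/dfE)/(SSR/dfR); the null distribution
  permutes grand-mean (reduced-model) residuals, 1000 iterations by
  default. All permutation p-values use (1 + #{F* ≥ F})/(n_perm + 1).
* **CS ANOVA.** Classical one-way F with Tukey HSD post hoc
  (Bonferroni-adjusted Welch tests available); levels with <2
  observations are excluded with a warning. Box-plot summaries (median,
  quartiles, 1.5·IQR whiskers, outliers) are emitted for size reporting.
* **Allometric trajectories.** Per group, OLS of the full PC score
  matrix on CS. Trajectory length is ‖slope‖ × (CS range of the group) —
  the magnitude of allometric variability the group spans; the length
  statistic is not precisely defined in the source workflow, so this
  definition is recorded here. Pairs are compared by the angle between
  slope vectors and by |length difference|, with p-values from shuffling
  group labels jointly for both statistics, CS held fixed. Caveat: when
  the two groups differ in mean size, permuted groups span the pooled CS
  range and fit slopes with more leverage, so the label-exchange null can
  flag noise-level angles; the test is calibrated (type-I error at
  nominal level) only under genuine exchangeability, which the test
  suite verifies.

## Classification

Two-class LDA (pooled within-class covariance) with leave-one-out
cross-validation; priors follow training-fold class frequencies by
default (the study's sexes are near-balanced), with an equal-priors
option. A singular within-class scatter in any fold triggers a logged
ridge-regularized refit. PC-count selection evaluates k = 1..10, keeps
the LOOCV-accuracy maximizer, and among ties prefers the smallest k whose
cumulative explained variance reaches 70%; if no k reaches the threshold,
the report carries a flag. LOOCV is pessimistically biased near chance at
small n (removing a specimen shifts its own class mean away from it), so
null-calibration checks use a chance band rather than an exact 50%
target.

## Synthetic data generator

The generator emulates the study conditions: two deformed-ellipsoid lobes
(radii ~8–16 mm, centres ±35 mm apart) carry the template structure, with
curve and surface budgets split between regions in the anatomical 6:19
and 37:64 proportions. Per specimen, lnCS ~ N(μ + s·male, σ); the shape
is the base geometry plus an allometric field scaled by (lnCS − μ), a
sex-specific field (males), a population field, and isotropic Gaussian
landmark noise, then re-standardized to unit centroid size, scaled to
exp(lnCS), and given a random rotation (det +1 only) and translation.
Effect fields are smooth low-frequency combinations of first-order
harmonics of the base coordinates — white-noise fields would be
unrealistically high-frequency for anatomy and would defeat sliding.

Defaults ("study-like"): cell sizes (24, 23, 29, 43, 10, 7) for (ER-F,
ER-M, SAR-F, SAR-M, SA-F, SA-M); lnCS sex shift 0.08 with σ = 0.05
(≈1.6 within-sex SD, the magnitude implied by the study's size
statistics); allometric field 10% of base CS per unit lnCS; sex shape
field 0.5% of base CS (subtle, so shape-only classification stays near
chance); population fields 0.8%; landmark noise 0.5 mm (digitization
scale). A "null" preset zeroes every effect for type-I-error
calibration.

What the generator does **not** emulate: real cortical surface geometry
(semilandmarks lie on smooth ellipsoid-like lobes), measurement error
correlated along the surface, asymmetries of preservation, or
population-specific allometry. Passing tests therefore demonstrate the
statistical machinery under the assumed generating model, not the
anatomical fidelity of any particular dataset.

## Problem sizes and determinism

Tests run on reduced designs (tens of specimens, the full 142-point
template or small toy templates) chosen to make the suite complete in a
few minutes; the acceptance script runs the full 136-specimen study-like
design with 999 RRPP permutations, 20 replicate form-vs-shape
comparisons, and 200 null replicates for calibration. Every stochastic
step takes an explicit seed; the pipeline derives per-test seeds from the
master seed through a counter, so adding an analysis never changes
existing numbers, and rerunning with the same seed reproduces every table
byte for byte.

## Known limitations

* Coordinate-only sliding cannot reproject onto the (unavailable) bone
  surface; heavily jittered semilandmarks can drift slightly off-surface
  within the displacement cap.
* One-way designs only; no two-way or nested Procrustes ANOVA, no
  phylogenetic or spatial corrections.
* Two classes only in the LDA (sex); no quadratic or shrinkage DA.
* Replication of the published specimen-level statistics requires the
  study's deposited raw coordinates, which are not redistributable here;
  the replication test activates when the files are placed under
  `data/replication/`.
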