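# Methods

This note records how the package computes what it computes, the
defaults that matter, and where the design was genuinely open.

## Geometry of a binary mask

All geometry runs on the mask's own voxel grid with physical spacing
`(sx, sy, sz)` in mm attached; origin and orientation metadata are
carried through I/O but never interpreted, because every feature here
is orientation-invariant. Any stored voxel value > 0 counts as
foreground, which tolerates label maps from external segmentation
tools. If a mask contains several 26-connected components, the largest
is analyzed and a warning issued (stray voxels are common in manual
segmentations).

**Volume** is foreground count × voxel volume, reported in mL so that
log-volume for tumors of a few cm lands in the low single digits.

**Surface area** has two estimators:

* *mesh* (default): marching cubes at level 0.5 in physical
  coordinates, after a Gaussian pre-filter (σ = 1 voxel) of the
  occupancy field. On a raw binary grid the triangulated area of a
  digitized ball overestimates the continuum `4πr²` by ≈ 8–9% at any
  radius — the staircase never averages out. With the pre-filter the
  measured ratio is 0.976 / 0.995 / 1.000 at r = 10 / 20 / 40 voxels,
  i.e. the estimator converges. The filter acts on the scalar field
  before iso-surfacing; no mesh-level smoothing is performed. Objects
  so thin that the filtered field never reaches 0.5 fall back to the
  face estimator with a warning.
* *face*: summed physical area of exposed voxel faces. For curved
  bodies this overestimates by a factor ≈ 1.5 (the ℓ¹-vs-ℓ²
  projection factor), which would push sphericity far below plausible
  tumor values — hence it is not the default — but it is exactly the
  quantity discrete compactness is built from, and is exact for
  axis-aligned boxes.

**Sphericity** `π^(1/3)(6V)^(2/3)/A` uses the mesh area by default and
is clipped at 1 (the voxelized estimate can exceed 1 by a fraction of
a percent for near-perfect balls).

**Discrete compactness** follows the contact-surface formulation: with
`n` unit-cube voxels and `A_c = (6n − exposed_faces)/2` shared faces,
`C_d = A_c / A_c,max` with `A_c,max = 3(n − n^(2/3))` (default), or the
fully normalized variant `(A_c − (n−1)) / (A_c,max − (n−1))`. The
count requires cubic voxels, so anisotropic masks are nearest-neighbor
resampled to an isotropic grid at the finest spacing component first
(configurable; CT slices are commonly 1–2.5 mm against ~0.7 mm
in-plane). A single voxel returns 1 by convention and the value is
clipped to [0, 1]. Reference values: any solid cube gives exactly 1; a
1×1×8 rod gives 7/12 (simplified) and 0 (full).

**Maximum Feret diameter** is the exact maximum pairwise distance
between physical centers of surface voxels, computed on the convex hull
vertices (the diameter of a point set is attained there; degenerate
flat sets fall back to brute force).

**Roundness** is `d_eq/d_max` with `d_eq = (6V/π)^(1/3)` (default), or
its cube `6V/(π d_max³)`; the ratio form stays in the band real tumors
print (≈ 0.55–0.82) for blob-like shapes, the cubic form is much more
aggressive (0.25 for a 1:1:2 ellipsoid vs 0.63 for the ratio).

## Statistical layer

* **Screening**: binary covariates → Pearson chi-square without
  continuity correction when every expected cell ≥ 5, otherwise
  Fisher's exact test (two-sided, point-probability rule); continuous
  covariates → pooled-variance Student's t (Welch by flag). Constant
  covariates are flagged with p = 1.
* **Odds ratios**: cross-product with Wald log-scale CI; zero cells get
  the Haldane–Anscombe 0.5 correction and a flag.
* **Logistic regression**: own IRLS with step-halving (the
  log-likelihood is monotone non-decreasing by construction),
  convergence at max |score| < 1e-8 or Δdeviance < 1e-10, standard
  errors from observed information. Continuous covariates are
  standardized internally and the coefficient vector and covariance
  back-transformed, so reported ORs are per original unit.
  Quasi-complete separation is declared when a standardized coefficient
  passes |β| > 15; by default this raises with the offending variable
  named, while cross-validation keeps the last stable iterate (a
  separable fold legitimately predicts near 0/1).
* **Stepwise selection**: backward from the full candidate set, removal
  of the largest-LRT-p variable while p > 0.10, re-entry of an excluded
  variable at LRT p < 0.05, ties broken by column order, a
  visited-model set guards against cycling. The LRT is used in both
  directions. Input order can affect the trace but not, generically,
  the final model.
* **LOOCV**: by default selection is run once on the full data and the
  selected model refit in each fold (this matches reporting a single
  final model); `selection_in_fold=True` re-runs the search inside
  every fold. Out-of-fold probabilities from refit models are
  *pessimistically* biased on null data (mean AUC ≈ 0.33 at n = 30, not
  0.5, because the left-out label anti-correlates with the training
  fit); tests therefore assert absence of spurious discrimination
  rather than AUC = 0.5 under the null.
* **ROC/AUC**: Mann-Whitney pair counting with ties at 1/2; curve by
  threshold sweep with "score ≥ threshold → invasive". AUC variance and
  the two-curve comparison use the DeLong placement-value estimator;
  measured null rejection rate is 0.050 (3000 replicates, n = 200).
  The AUC confidence intervals are normal-approximation DeLong
  intervals; narrower interval constructions exist, so published AUC
  CIs are not comparison targets.
* **ICC**: two-way random-effects, absolute-agreement, single-rater
  form `(MSR − MSE)/(MSR + (k−1)MSE + k(MSC − MSE)/n)` with the
  McGraw–Wong F-based CI; bands ≤ 0.40 poor, (0.40, 0.60] moderate,
  (0.60, 0.80] good, > 0.80 excellent. Degenerate inputs (zero subject
  variance) are flagged rather than imputed.
* **Sample size for a correlation**: Fisher-z,
  `n = ⌈((z_α + z_power)/atanh ρ₀)² + 3⌉`, floored at 4. Sidedness is
  **one-sided by default**: the published protocol's n = 16 at
  ρ₀ = 0.60, α = 0.05, power 0.80 corresponds to the one-sided z
  (two-sided gives 20), and the original report does not state
  sidedness.

## Synthetic data

Phantoms are rasterized spheres/ellipsoids; a lobulated phantom
modulates the radial threshold with `n_lobes` Gaussian angular bumps at
seeded random directions, lobes rising to `(1 + 0.6a)R` and the valleys
between them sinking to `(1 − 0.4a)R` at amplitude `a` — so amplitude
raises surface waviness rather than just size, and amplitude 0 is the
base shape exactly. Mean discrete compactness decreases monotonically
in amplitude (measured 0.985 → 0.971 over amplitudes 0 → 0.9 at
r = 10). The shapes remain star-shaped and 26-connected.

The second-reader generator perturbs the boundary by eroding surface
voxels and dilating the adjacent background, each with per-voxel
probability `noise/(noise + 4)`, but the decisions are thresholded from
a smoothed (σ = 5) Gaussian random field so that disagreement forms
coherent patches the way human readers over/under-include a region.
Independent per-voxel flips were rejected: they shred the contact
surface and drive compactness agreement to ICC ≈ 0, which no two
plausible readers of the same tumor would produce. With the
patch-based model a 16-subject study at noise 1 lands all five feature
ICCs above 0.8, the regime the real inter-observer test reported.

Cohort simulation draws, per class, binary covariates as Bernoulli and
continuous features as normals truncated by resampling (unit-interval
features to (0, 1], sizes to positive); the default parameters are the
published per-class prevalences and means/SDs (23 encapsulated vs 30
invasive; cystic change 3/23 vs 16/30; discrete compactness
0.825 ± 0.106 vs 0.691 ± 0.160; and so on). Features are independent
within class — the source tables print no covariances — with an
optional Gaussian-copula correlation matrix; this independence is a
known unrealism. Sub-seeds derive from the master seed with
counter-based spawn keys, so extending a cohort never changes earlier
subjects.

**What passing tests show, and don't.** The phantom cohorts demonstrate
that the pipeline recovers a planted geometric difference end to end
(lobulation gap → compactness gap → combined model beats the clinical
model in essentially all seeds). They do not certify performance on
real CT: phantom compactness spans a much narrower band (≈ 0.94–0.99)
than real tumors (0.37–0.93), there is no partial-volume effect, no
intensity information, and reader disagreement is a stochastic model
rather than human behavior.

## Problem sizes and numerical choices

Simulation-backed checks use: 500 replicates at n = 200 for DeLong null
calibration; 100 seeds at n = 200 for stepwise retention of an OR ≈ 7
effect; 50 seeds of 12 + 12 phantom cohorts (base radius 7–12 voxels)
for the end-to-end ordering; 16 subjects for the two-reader study,
matching the protocol's computed sample size. These sizes give stable
Monte-Carlo estimates while keeping a full run around a minute.
Tolerances in tests come from the printed precision of published
values (three decimals for ORs), from closed forms (exact for cube and
rod counts), or from measured voxelization error at the stated radii.

## Known limitations

* The mesh pre-filter (σ = 1 voxel) erases genuine surface detail
  below ~2 voxels; features of very small or very thin objects are
  resolution-limited.
* Discrete compactness depends on the resampling target for anisotropic
  masks; comparisons across scanners should fix the target spacing.
* The stepwise procedure inherits the usual caveats of data-driven
  selection (optimism, instability at small n); LOOCV mitigates but
  does not remove optimism when selection is run once on the full data.
* Separation is surfaced, not penalized: for quasi-separated data a
  Firth-type fit would give finite estimates, which is out of scope.
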