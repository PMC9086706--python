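# Methods

## The phantom model

A subject's left atrium is modeled as an ellipsoidal endocardial chamber
with semi-axes in fixed ratio 1.12 : 1.00 : 0.90 (axis ratio 1.244, kept
below 1.25 so normal offsets stay well-conditioned). The wall is swept
outward from the inner surface along the outward normal by a
direction-dependent thickness field

    T(u) = mu_T + sigma_T * (P0(u) - m) / s

where u parameterises the surface by the unit sphere, P0 is a sum of
Gaussian angular bumps ("patches"), and (m, s) are the area-weighted
mean and SD of P0 over the *mapped* region. By construction the
area-mean of T over the mapped region is exactly mu_T and its area-SD
exactly sigma_T, so mean wall thickness and wall-thickness heterogeneity
have analytic ground truth.

Five spherical caps in direction space — four pulmonary-vein ostia on
the posterosuperior aspect (polar 50°, azimuths 45/135/225/315°) and one
mitral-annulus cap at the inferior pole — are excluded from the mapped
wall (voxel label 3). Their joint aperture scale is solved by bisection
so the mapped offset-shell volume equals the subject's target wall
volume; the caps stay pairwise disjoint up to scale 1.40, which bounds
the reachable mapped fraction at about 0.41 from below.

Ground-truth volumes use exact normal-coordinate quadrature: the shell
volume over a region R is ∫_R [T + T²(κ₁+κ₂)/2 + T³κ₁κ₂/3] dA with
principal curvatures from the implicit-surface formulas (verified
against concentric spheres to machine precision). Chamber volume is
4/3·π·abc in closed form. Quadrature uses Gauss–Legendre × uniform
azimuth rules: 48×96 nodes on the full sphere, 12×24 per cap with
boundary-conforming support, so cap-edge discontinuities never cross a
quadrature cell.

Voxelization classifies each lattice point by its exact foot point on
the inner ellipsoid (Newton on the standard largest-root equation,
monotone from t=0 for exterior points): chamber inside the ellipsoid,
wall/excluded-wall when the Euclidean distance to the foot point is at
most T at the foot direction, background otherwise. A certified
exterior band — dist ≥ (q−1)·a_min²/(2|x|) — limits the Newton solve to
voxels that can possibly be wall.

### Why the field minimum is floored at one voxel

The sampler redraws any subject whose thickness field dips below
1.02 × spacing. Signed distance to the inner surface is 1-Lipschitz, so
with T ≥ h no background voxel can share a face with a chamber voxel;
a wall thinner than one voxel can leave the voxelized chamber
unenclosed. The floor implies the weaker half-voxel invariant on the
continuous field.

## Cohort calibration

Wall indices (LAVi, LAWV, LAWT, LAWT(SD)) are modeled log-normal,
fitted exactly to published group medians and quartile ratios
(mu = ln median, sigma = ln(Q3/Q1)/(2·0.67449)); right-skewed
laboratory covariates (hs-CRP, BNP) likewise. Echo covariates are group
Gaussians from published means/SDs; binary covariates are Bernoulli at
the published prevalences. BSA, not reported, is Normal(1.73, 0.15)
truncated to [1.2, 2.6] m².

Two couplings shape the joint distribution; both are Gaussian copulas,
so every marginal law is preserved exactly:

1. **LAVi–PALS.** The within-group latent correlation is found by
   bisection so the *pooled* standardized slope of PALS on LAVi (which
   decomposes into a between-group part fixed by the group means and a
   within-group part linear in the latent correlation, using
   Cov(e^{μ+σZ₁}, Y) = ρσ·E[X]·SD(Y)) equals the configured −0.43.
   The solved latent correlation is ≈ −0.25.
2. **LAWV–(LAV, LAWT).** Wall volume scales with chamber surface area
   times thickness, so log LAWV is coupled at latent correlation 0.97
   to (2/3)·log(LAVi·BSA) + log(LAWT). This is the construction-induced
   coupling: it keeps the implied mapped fraction
   f = LAWV / V_full more than 3 SD inside its (0.5, 0.95) window in
   every group, so the bounded redraw rule is a guard rather than a
   truncation and group medians stay within 1% of their calibration
   targets. Other cross-index correlations are left at independence.

The redraw loop (at most 100 attempts, violations named in the error)
also enforces the thickness floor and the self-intersection bound
(maximum offset below the minimal curvature radius a_min²/a_max).

## The wall-mapping engine

Thickness is sampled once per chamber-adjacent wall voxel — an
approximately area-uniform sampling of the mapped surface — as
t(p) = d_ch(p) + d_bg(p) − h with both distances from exact Euclidean
distance transforms. d_ch is always exactly h at a sample voxel, and on
a k-voxel slab the decomposition returns exactly k·h: it carries no
half-voxel bias. Samples 6-adjacent to excluded-wall voxels are
dropped and counted. 6-connectivity (face adjacency) defines all
boundary notions. Population (not sample) SD is used for LAWT(SD), for
bit-reproducibility at any sample count.

The transforms run on the bounding box of non-background voxels padded
by one layer; clamping any outside background voxel coordinate-wise
onto the pad shell can only decrease its distance to an interior voxel,
so the cropped transform equals the full-lattice transform at every
sample.

**Estimator noise floor.** A sample voxel's centre sits at a random
depth (0, h) inside the wall while d_ch is pinned at h, so individual
samples carry a depth-quantization error with SD ≈ 0.28·h (measured
0.1415 mm on a uniform 2 mm sphere at h = 0.5). Cohort means are
unbiased to well under half a voxel, but LAWT(SD) is inflated by this
noise in quadrature, and the between-subject regression of measured on
true LAWT(SD) has a structural R² ceiling of ≈ 0.975–0.985 at 0.5 mm —
the recovery tests assert R² ≥ 0.97 for that index and ≥ 0.98 for the
others. Mean thickness carries a small negative bias (≈ −0.1 mm at
h = 0.5) from the same geometry; it stays inside the half-voxel bound.

The 3D projection map is exported as a CSV point cloud (one record per
sample) and an ASCII PLY surface with a per-vertex `thickness` scalar,
triangulated by the convex hull of the sample cloud — adequate for the
convex phantom chambers, not for concave real anatomy.

Anisotropic volumes are rejected at load (1% tolerance); invariant
violations (unknown labels, open chamber) are reported with voxel
coordinates, never repaired.

## Statistics

- **Test routing**: Shapiro–Wilk per group at α = 0.05; any failing
  group routes the variable to Kruskal–Wallis / Mann–Whitney (exact p
  for small tie-free samples via scipy), else ANOVA / t-test.
  Categorical: Fisher's exact when a 2×2 expected cell < 5, else
  chi-square with Yates correction. Routing is a pure function of the
  data; summaries follow the test family (mean ± SD vs median [IQR]).
- **C-statistic**: midrank (tie = 1/2) AUC; variance by DeLong's
  structural components; cutoff maximizes Youden's J over observed
  thresholds with ties broken toward higher specificity.
- **Continuous NRI** is defined on the risk scale: when a marker is
  "added to" a base variable, both scores are fitted event
  probabilities from unpenalised logistic models (base alone vs base +
  marker). Significance by a seeded 2000-permutation null of the event
  labels (the source analyses report NRI p-values without a method).
- **MIC**: grid resolutions i×j with i·j ≤ n^0.6 (axis cap 15); one
  axis mass-equipartitioned, the other optimized by an exact dynamic
  programme on the additive decomposition
  I = H(rows) − Σ_cols (m_col/n)·H(rows|col); both orientations;
  normalized by log₂ min(i, j). Runs of equal values are never split;
  beyond 64 clumps they are merged into at most 15·i superclumps by
  mass equipartition, so the search is exhaustive for n ≤ 60. The
  nonlinearity flag is exactly MIC − r² ≥ 0.1. A numba-accelerated and
  a pure-numpy backend produce identical results.
- **Variable clustering**: pairwise MIC proximity, distance 1 − MIC,
  average linkage. The proximity/linkage choice is recorded in the
  output metadata.
- **Matching**: greedy 1:1 nearest-neighbour without replacement on
  Mahalanobis distance (covariance from the stacked samples); singular
  covariance falls back to SD-normalized Euclidean with a warning;
  standardized mean differences reported before/after. Default
  covariates: age, sex, BMI, hypertension, diabetes, E/e′
  (config-overridable — the "key clinical covariates" are not
  enumerated in the source).
- **Adjusted medians** (method unstated in the source; one defensible
  reading, recorded in output metadata): residualize the variable on
  the covariates pooled across groups, add back the grand mean, report
  per-group median [IQR]. When covariates are group-confounded this
  adjustment absorbs part of the group effect into the covariate slope.

## The study pipeline

`run_study` executes generate → map → analyze with one configured seed:
four-group comparisons of the indices, ROC of each index for AF-alone
vs controls+HFpEF-alone (HFpEF+AF excluded, so the discrimination
subset is always total − n_HFpEF+AF), NRI of LAWV and LAWT(SD) added to
LAVi and PALS, MIC screening of each index against PALS, variable
clustering, LAWT(SD) contrasts stratified at LAVi 40 ml/m² (the
published threshold, fixed rather than recomputed, config-overridable),
and the 1:1 matched comparison. Result JSONs are byte-reproducible
under a fixed seed; tables echo result files exactly and mark missing
analyses as absent.

Default lattice: 0.5 mm isotropic on 160³ (CT-like). A subject whose
geometry cannot satisfy the 2-voxel background margin gets the smallest
even cubic grid that can hold it — upper-tail HFpEF+AF chambers exceed
80 mm; truncating or redrawing them would bias cohort medians.
Stratified contrasts with fewer than 3 subjects in a cell are recorded
as skipped with the reason, not fabricated.

## What the generator does and does not emulate

Passing tests show that the measurement engine recovers known geometry
and that the statistics match their oracles under calibrated,
log-normal/Gaussian, smooth-ellipsoid conditions. Real atria differ in
ways the phantom deliberately omits: concave regional anatomy
(appendage, PV funnels, crista terminalis), segmentation error in the
input labels, anisotropic CT sampling, within-subject covariate
structure beyond the two calibrated couplings, and any genuine
nonlinear LAVi–PALS relationship (the copula induces a monotone one).
Results on real data therefore depend on upstream segmentation quality
in a way these tests cannot certify.

## Problem sizes

Default test and acceptance runs use the published group sizes (115 /
59 / 37 / 38) at 0.5 mm — about one second per subject — with 10⁴-draw
checks for sampling fidelity and 200–1000-replicate simulations for
the statistical calibration checks; smoke tests of the full pipeline
use 8-subject groups on 64³ lattices at 1 mm.
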