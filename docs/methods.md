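# Methods

This note records the model, the numerical choices, and what the
synthetic experiments do and do not establish.

## The bi-tensor free-water model

Each voxel's diffusion-weighted signal is modelled as a two-compartment
mixture:

S_k = S0 · [(1 − f) · exp(−b_k g_kᵀ D g_k) + f · exp(−b_k d_w)],

where D is the tissue tensor (symmetric positive definite), f ∈ [0, 1] is
the free-water volume fraction, and d_w is the diffusivity of free water.
d_w = 3.0×10⁻³ mm²/s (free water at body temperature) — the literature
convention; it is a fixed constant, not a fitted parameter.

### Identifiability and constraints

With a single shell (one nonzero b-value) the model is not identifiable
without constraints: for isotropic tissue the per-voxel problem has a
one-parameter family of exact solutions, and even for anisotropic tissue
the (f, D) likelihood surface has an extremely flat valley, because a
tensor with inflated eigenvalues can imitate most of the water
compartment's attenuation. Three constraints make the problem workable:

* tensor eigenvalues confined to [0.1, 2.5]×10⁻³ mm²/s (a physiological
  band for brain tissue);
* f confined to [0, 1];
* an optional spatial penalty λ·Σ‖∇f‖² over the fitting mask
  (`lambda_reg`, default 1.0; 0 disables).

The spatial penalty here is a simple quadratic first-difference penalty
on the 6-neighbourhood graph, solved by Jacobi sweeps — a deliberately
plain, documented alternative to gradient-flow schemes; the contract of
this fit is parameter recovery on synthetic data, not bit-agreement with
any particular legacy implementation.

### Optimizer

All work happens in attenuation space (signal normalized by the voxel's
mean b=0 signal). For fixed f the optimal tensor has a closed form (the
standard log-linear tensor regression on the water-subtracted
attenuation, followed by eigenvalue clipping), so the objective can be
profiled down to a 1-D function of f. That profile is minimized per voxel
by a deterministic grid scan (`n_profile` = 21 points) plus
golden-section refinement (`n_golden` = 12 steps, final bracket ≈ 7×10⁻⁴
wide), then polished by a few block-coordinate steps (`max_iter`,
convergence when the objective decrease falls below `tol` = 1e-10).
Plain alternating descent without the profile scan stalls in the flat
valley; the scan finds its global minimum reliably on noise-free data.

With λ > 0, `n_outer` = 10 outer iterations alternate the per-voxel data
update (closed-form optimal f given the current tensors, with its
curvature) with Jacobi smoothing sweeps, then refit the tensors.

The fit is fully deterministic; `FitConfig.seed` is reserved for any
future randomized initialization and is not consumed by the default path.

### What the fit can and cannot do

* Noise-free, anisotropic tissue: recovery is essentially exact over the
  whole f range (max per-region mean error ~1e-4 in the acceptance run).
* Noise-free, isotropic tissue (GM/CSF-like): non-identifiable by
  construction; estimates there are arbitrary within the solution family
  and must not be interpreted. The measurement masks are white matter
  only, so this does not touch the reported metrics.
* Rician noise at SNR 30 (σ = S0/30): the voxelwise least-squares
  estimate is weakly identified — the unconstrained minimum frequently
  sits at the f = 0 corner because the 6-parameter tensor absorbs the
  water signal. The spatial penalty is what makes the field estimate
  usable (WM RMSE drops from ≈0.17 to ≈0.035 at λ = 1 in the acceptance
  run). Small structures (1–2 voxel lesions) are underestimated at this
  SNR because both the data and the smoothing pull them toward the
  surrounding baseline; group-level contrasts, which average over
  hundreds of voxels and many subjects, remain reliable (the end-to-end
  cohort check recovers the constructed group ordering in 20/20 seeded
  repeats).

Unfittable voxels (non-positive S0, all-zero or non-finite signal)
propagate as NaN, never as 0, so downstream means are computed over valid
voxels only and are not biased downward.

## Masks

Structuring elements are discrete Euclidean balls: offsets v with
‖v‖₂ ≤ n ("radius n" read literally); a cube (Chebyshev) variant exists
for sensitivity checks. The safe-WM mask is exactly

WM_safe = ((WM − (GM ⊕ R1)) − (CSF ⊕ R1)) ∩ (BM ⊖ R15)

with set subtraction A − B = A ∧ ¬B. Erosion treats out-of-grid voxels
as background, so the brain-mask erosion also recedes from the
field-of-view edge — conservative for partial-volume safety. The WMH
penumbra exclusion is a single radius-2 ball dilation of the lesion mask
(not two iterated radius-1 dilations, which differ on a discrete grid).

Radii are voxel units of the working grid. The default r_brain = 15
presumes a full-size brain on a ~1 mm grid; the synthetic phantoms are
tens of voxels across, so phantom-scale helpers default to r_brain = 3.
All three defining postconditions (disjoint from the GM and CSF halos,
inside the eroded brain mask) are asserted on every acceptance run with
the radii actually used.

Tissue maps are hard binary labels; probabilistic segmentations must be
thresholded upstream (at 0.5). WM/GM/CSF overlap triggers a warning with
the overlap count, not an error.

## Metrics

rFW uses a strict inequality (FW > 0.1): a voxel at exactly the threshold
does not count. The threshold is configurable (`threshold`, default 0.1)
with a sweep utility, since its appropriate value is dataset-dependent.
μFW averages *all* valid mask voxels, including those below the rFW
threshold — the plain reading of a mask mean. The per-subject summary
reports four masks: raw WM, WM_safe, the *undilated* lesions (the
lesion-FW measurement is about the lesions themselves), and WM_safe minus
the *dilated* lesion mask (measurement in normal-appearing WM requires
the penumbra removed).

## Cohort statistics

* Log transform: natural log. Pairwise differences are therefore on the
  natural-log scale; base only rescales printed magnitudes.
* ANOVA: classical between/within sums of squares.
* Post-hoc: Tukey–Kramer (unequal group sizes), se =
  √(MSW·(1/nᵢ + 1/nⱼ)/2), p from the studentized range distribution with
  (k, N − k) degrees of freedom. Pair order is fixed as (NC, MCI),
  (NC, AD), (MCI, AD), so a negative NC − patient difference means the
  patient group is elevated.
* ANCOVA: OLS of log(metric) on group indicators (NC reference), age and
  a 0/1 gender indicator; with no interaction terms the group contrasts
  are the adjusted (mean-age, gender-balanced) differences. Rank
  deficiency (e.g. a constant covariate) is an error naming the culprit.
* Stars: * p < 0.05, ** p < 0.01, *** p < 0.001; no multiple-testing
  correction across metric rows (deliberately, matching the reporting
  convention the report mirrors).
* A metric column containing zeros (possible for WMH volume when a
  subject has no lesions) cannot be log transformed; the report analyses
  it on the raw scale and flags this in its `scale` column.

## Z-score cluster maps

Reference mean and SD are per-voxel sample statistics (divisor n − 1)
over the NC group; voxels with any missing value or zero SD are excluded
from the valid set. Subject z-maps are averaged within the patient group,
thresholded at z ≥ 2 (inclusive) on the positive tail (elevated FW is the
direction of interest; a two-tailed flag exists), labelled under
26-connectivity (configurable 6/18/26), and components below 10 voxels
are discarded. Which subjects are z-scored against which reference is
exposed as parameters; the default is each patient group against the NC
reference.

## Synthetic data

The phantom is stylized, not anatomical: nested ellipsoids (brain; a
2-voxel cortical GM shell; central CSF ventricles; WM between), with
spherical WMH lesions carved from the WM interior. True FW: 0.15 baseline
in WM, +0.25 ramp within 3 voxels of CSF (emulating partial-volume
contamination so that WM and WM_safe genuinely differ), 0.6 in lesions,
0.25 in GM, 1.0 in CSF. WM tensors are axially symmetric with eigenvalues
(1.5, 0.4, 0.4)×10⁻³ mm²/s and a principal axis that rotates smoothly
across the volume; GM and CSF are isotropic (0.8 and 3.0 ×10⁻³). The DWI
protocol mirrors the target acquisition: one b=0 volume plus 41
Fibonacci-sphere directions at b = 1000 s/mm². Noise is Rician
(magnitude of a complex Gaussian perturbation), default σ = S0/30.

Cohorts default to group sizes 81/103/42 (NC/MCI/AD) and additive WM
baseline offsets (0, +0.02, +0.04) with per-subject Gaussian jitter of SD
0.005 — chosen so within-group spread stays well below the between-group
separation, a realistic regime for a measurement intended to separate
groups. Lesion counts are Poisson with group-dependent means (1.5, 2.5,
3.5), so lesion load grows along the disease spectrum. The ground-truth
metric table is computed by applying the metrics layer to each subject's
*true* FW field — never to a fit — so it is an exact oracle for the
pipeline output.

What passing synthetic tests does **not** show: robustness to scanner
artifacts, motion, eddy currents, imperfect registration or segmentation,
multi-site effects, or anatomy-dependent partial-volume geometry. The
phantom establishes algorithmic correctness (mask algebra, metric
definitions, statistics, direction of group effects), not clinical
validity.

## Problem sizes in the standard checks

The acceptance run uses a 40³ phantom for the noise/regularization
comparison, 100 random 12³ masks for the morphology oracles, 1,000
resampled null cohorts at sizes 81/103/42 for the type-I rate, and 20
seeded end-to-end cohorts of 20/20/20 subjects on a 20³ grid with offsets
(0, +0.03, +0.06) for direction recovery — sizes chosen so the whole run
completes in a few minutes on one CPU while keeping every group
comparison at full cohort-scale sample sizes where it matters (the
statistics layer).

## Known limitations

* Per-voxel FW at realistic single-shell SNR is prior/regularization
  driven; absolute voxel values should be interpreted cautiously, and
  small-lesion FW is underestimated (see the fit section).
* Multi-shell and multi-fiber models are out of scope.
* Registration, segmentation and WMH delineation are upstream
  responsibilities; all inputs must arrive co-registered on one grid.
* The z-score cluster procedure performs no multiple-comparison
  correction; it is a descriptive visualization, not inference.
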