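# Methods

This note documents the models, the synthetic data, the numerical choices
and the limitations of `pmihub`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Pipeline model

**Inputs.** Per subject: a free-water volume-fraction map (scalar in [0, 1])
with co-registered binary tumor-core and edema masks, all NIfTI-1 on one
grid. Volumes are resampled to the working resolution of 2×2×2 mm
(trilinear for the scalar map, nearest-neighbor for masks; world extent
preserved). Overlapping mask voxels are assigned to the tumor core — the
pipeline must never treat core tissue as edema. All geometry downstream
(sizes, diameters, sdvec) is in working-grid voxel units.

**Patch classifier.** 16×16 in-plane patches are sampled at uniformly random
edema centers and cardinal planes (axial/sagittal/coronal) with rejection;
base patches must lie fully inside edema. Shift augmentation moves a patch
in-plane by an integer offset drawn uniformly from [−4, 4]², accepting
placements with at most 20% of the window outside edema and none inside the
core. Patch values are raw free-water fractions; the only preprocessing is
one fixed affine map (x − 0.5)/0.25 applied identically to every input —
constants of the data range, chosen so activations are well-scaled for the
small learning rate. No per-patch normalization is applied anywhere: the
absolute free-water level *is* the class signal.

The network is six **valid** (unpadded) 3×3 convolutions with ReLU
(channels 8, 8, 16, 16, 32, 32), one 2×2 max-pool, and a fully connected
2-way softmax head; on a 16×16 patch the valid stack shrinks the grid to
4×4, the pool to 2×2. Valid convolutions are deliberate: they make the
network exactly translation-covariant, so one pass of the conv stack over a
whole (zero-padded) slice yields the logits of *every* patch position
(`CNN.dense_logits_batch`), which is what makes voxel-wise PMI maps
tractable on a single CPU core. The test suite verifies the dense path
against the per-patch path to float32 precision, and backpropagation against
finite differences.

Training is plain SGD: momentum 0.9, weight decay 5·10⁻⁵, initial learning
rate 10⁻⁴, batch size 16, 8–12 epochs, an internal 80/20 held-out split
reported in the `TrainReport`. The small batch size compensates for the
desk-scale patch corpus (thousands rather than the very large clinical
corpus such a study would collect): at a fixed learning rate the relevant
budget is SGD steps, not epochs. Channel widths are half of the widest plan
consistent with the architecture description; the halved plan shows no
accuracy loss on the phantom task at a quarter of the cost, and both width
and epochs are configuration, not contract.

**PMI map.** For every edema voxel the three cardinal 16×16 patches centered
there are evaluated (volume zero-padded by 8 voxels per side so border
patches are defined) and the probability of the low-free-water
(infiltrative) class is averaged: PMI ∈ [0, 1], high = infiltrative-looking,
NaN outside edema.

**Hubs.** Supra-threshold field `PMI ≥ τ` (closed, so PMI = 1 survives
τ = 1.0) restricted to edema, labeled with 26-connectivity (6/18/26
configurable); components with diameter < 2 voxels removed. Diameter is the
maximum pairwise voxel-center distance (bounding-box diagonal available as a
config alternative), computed via the convex hull for large components with
a bounding-box shortcut when the filter decision is already determined. Each
hub carries its size, centroid (unweighted mean coordinate) and *sdvec*, the
per-axis **population** (1/N) standard deviation of member coordinates.

**Threshold selection.** For each τ in {0.0, 0.1, …, 1.0} the five markers
are computed per validation subject and compared between the two classes
with pooled-variance t tests. Only markers defined for *all* subjects at
that τ are scored. The chosen τ maximizes the count of markers with
p < 0.05, ties broken by the smallest mean log₁₀ p, then by the smaller τ.
On phantom validation sets of 10 + 10 subjects the choice concentrates on
the upper grid (0.8–0.9), where all five markers become computable; which of
the two adjacent values wins can depend on the validation sample, since the
shape/directional p-values sit near the 0.05 boundary at this sample size.

**Markers.** With sdvec components sorted s₁ ≥ s₂ ≥ s₃ per hub:

* number of hubs / edema voxels, and mean hub size / edema voxels;
* shape heterogeneity = mean over hubs of (s₁ − s₂)/s₁ (0 isotropic,
  1 line-like; hubs with s₁ = 0 contribute 0);
* directional heterogeneity = max over hubs of the minimum pairwise cosine
  distance 1 − cos(sdvecᵢ, sdvecⱼ), j ≠ i. This is the max–min reading of a
  Hausdorff statistic on a single direction set: the literal two-set
  Hausdorff distance of a set with itself is identically zero, so
  self-matches are excluded. Range [0, 2]; zero-sdvec hubs are excluded with
  a warning;
* spatial heterogeneity = mean pairwise centroid distance divided by the
  edema diameter (the maximum possible distance between any two edema voxel
  centers — using the realized centroid span instead would force every
  two-hub subject to exactly 1). Clipped to (0, 1]; coincident centroids
  yield a flagged 0.

Markers requiring ≥ 2 hubs are NaN below that; such subjects are removed by
the exclusion step (reasons `small_edema` for < 2 edema voxels,
`too_few_hubs` for < 2 hubs), mirroring the cohort filtering a clinical
analysis would apply, rather than imputed.

**Cohort statistics.** Median survival split assigns the median subject to
the *short* group. Group tests: pooled-variance two-sample t test or
Wilcoxon rank-sum via the normal approximation with tie correction;
Bonferroni factor fixed at 5 (the five markers), adjusted p = min(1, 5p).
Covariate-adjusted analysis: OLS of each marker on the group indicator plus
age and sex (both categorical covariates use the alphabetically first level
as reference). Clustering: K-means (10 restarts) on z-scored markers,
Calinski–Harabasz over k = 1..9 (k = 1 undefined → −∞). The two-cluster
solution is always computed and named low-/high-PMI by mean directional
heterogeneity (higher → high-PMI); the survival contrast is defined on it,
with the CH-chosen k reported as a structure diagnostic — on
continuum-structured marker tables CH can prefer large k, whereas planted
two-cluster tables are recovered as k = 2. Naming uses directional rather
than shape heterogeneity because the phantoms' boundary-zone hubs make shape
anisotropy geometry-dependent, while directional heterogeneity is robustly
higher for infiltrative subjects and is also the poor-prognosis direction.
Survival: Kaplan–Meier product-limit curves (the right-censoring special
case to which the general nonparametric interval-censoring estimator
reduces), two-group logrank, and a Cox proportional-hazards fit on the
binary cluster indicator with Efron tie handling (via lifelines), HR with
Wald 95% CI.

## Phantom design

A phantom subject is an ellipsoidal tumor core (radius 5 voxels, per-axis
jitter up to ×1.2, center jitter ±2 voxels) inside an edema shell
(thickness 20 voxels) on a 64³ grid at 2 mm spacing. Free water: healthy
background 0.15, core 0.5, vasogenic edema 0.8, restricted pockets 0.3;
additive noise is white Gaussian smoothed with a 1-voxel Gaussian kernel
(σ = 0.05), so the phenotypes cannot be told apart by pixel-level noise
statistics. Pockets — spheres of radius 2.5 placed fully inside edema with
rejection (error after 1000 consecutive rejections) — are the *only*
systematic difference between phenotypes; they are exactly what the
classifier must learn.

Two named condition sets mirror a train/test cohort split:

* **training condition** (`training_spec`): 150 pockets (~15–20% of edema),
  unconstrained placement. Dense pockets make diagnosis-labeled patches
  separable — with sparse pockets most "infiltrative" patches would contain
  no pocket and the patch task would be unlearnable at any capacity.
* **analysis condition** (`analysis_spec`): 12 pockets kept ≥ 5 voxels
  (≈ the patch half-width) clear of the edema boundaries. Patch-support
  bleed across mask boundaries elevates PMI in a ~patch-half-width zone
  along both edema surfaces in *all* subjects (healthy brain and core both
  present low-free-water context); the 20% shift augmentation reduces but
  cannot remove this, because inference patches at the boundary carry far
  more than 20% outside-edema support. The margin keeps planted pockets
  resolvable as distinct interior hubs instead of merging with that boundary
  zone. The boundary-zone hubs themselves appear consistently in both
  phenotypes and therefore do not drive group differences.

Cohorts: per-subject infiltration burden = pocket voxels / edema voxels
(exactly recomputable from the returned truth mask); infiltrative subjects
draw their pocket count uniformly in [½·12, 1½·12] so burden is graded.
Survival time is exponential with hazard (1/14 per month) ·
exp(log 2 · z), z the within-cohort standardized burden — so a Cox fit on
standardized burden has the known target HR 2 per SD. Censoring is an
independent exponential whose rate is solved (Brent) so the expected
censored fraction equals the requested rate (default 0.3). Everything is
reproducible from the cohort seed.

What the phantoms do *not* emulate: anatomy, white-matter tract geometry,
bias fields, scanner noise, registration error, multi-focal tumors, and any
direct biological link between edema microstructure and survival — the
survival signal is planted by construction. Passing tests therefore show
that the pipeline recovers planted structure of the stated kind and size;
they do not show clinical validity on real cohorts.

## Problem sizes and numerical choices

The suite and acceptance script use: 2000 patches/class (10 training
subjects per class, 150 base + 50 augmented patches each) for classifier
checks; 10 + 10 subject validation sets for threshold selection; 40-subject
cohorts (10 replicate seeds in the suite, 3 in the acceptance script) for
the end-to-end survival recovery; 200 replicates at n = 264 with ~30%
censoring for Cox CI coverage and logrank null calibration. These sizes are
the package's chosen desk-scale study conditions; the phantom geometry
(64³) is the smallest on which 16×16 patches fit inside edema with an
interior pocket band left over.

Numerics: all CNN math in float32; He initialization; ties in max-pool
backprop split evenly; softmax computed with max-subtraction;
`point_set_diameter` exact (hull vertices, then brute force); thresholding
closed (≥); marker tolerances in tests 1e-9 where arithmetic is exact.
Degenerate inputs: empty edema → empty PMI map with warning; no hubs →
zero count/size markers and flagged heterogeneity markers; zero-variance
markers in group tests → p = 1 with a flag; all-identical survival times →
hard error on the median split.

## Known limitations

* The patch classifier reduces, on phantoms, to a detector of locally
  lowered free water; real infiltration differs from vasogenic edema in
  richer ways the phantom does not model.
* PMI near mask boundaries is biased upward by patch-support bleed (see
  above); analyses should treat boundary hubs as a systematic feature, as
  the marker analyses here do.
* The Hausdorff-style directional statistic, the (s₁−s₂)/s₁ shape
  normalization and the edema-diameter spatial normalizer are the package's
  documented readings of underdetermined definitions; alternatives (e.g.
  bounding-box diameters, sample SD) are exposed in configuration where
  meaningful.
* With 10 + 10 validation subjects the selected hub threshold can vary by
  one grid step between samples; larger validation sets stabilize it.
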