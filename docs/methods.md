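# Methods

This note documents the models, defaults and design choices behind
`radharm`, and what the synthetic cohort does and does not establish.

## Data model and geometry

A study is a 3D grayscale volume with an integer-label mask (0 background,
1 LV cavity, 2 myocardium, 3 RV cavity), voxel spacing `(dx, dy, dz)` in
mm, and centre / pathology / phase metadata. Arrays are indexed
`(slice, row, col)`.

Before extraction every study is resampled in-plane to 1 × 1 mm (the
common spatial grid radiomic features implicitly assume); slice count and
thickness are left untouched because short-axis stacks are heavily
anisotropic (≈10 mm slices) and through-plane interpolation would invent
signal. Images are interpolated bilinearly; masks by nearest neighbour,
which provably cannot create labels absent from the input. The
interpolation kernel is a package choice — linear is the least-surprising
default for magnitude images.

## Synthetic multi-centre cohort

The generator emulates the *statistical* structure of a multi-centre
cardiac cohort, not anatomy:

* **Phantom.** Per slice: an LV disc, a concentric myocardial ring and an
  RV crescent on a darker background, rendered on a canonical [0, 1]
  scale. Default volume 3 × 64 × 64 (kept small so texture-matrix tests
  stay fast). ES frames shrink the cavity by 20% and thicken the wall by
  15% — a crude systole.
* **Disease effect.** HCM doubles the mean myocardial wall thickness
  (8 px vs 4 px, sd 1.0/0.6) and alters myocardial texture: the
  myocardium carries a Gaussian random field smoothed in-plane with
  σ = 1.6 px (vs 0.8) and sd 0.10 (vs 0.05). Both geometry and
  second-order texture therefore carry class signal, and the texture
  component survives any monotone intensity normalisation — mirroring
  the clinical intuition that hypertrophic cardiomyopathy is most
  visible in the myocardium.
* **Centre effect.** `out = M · (g · xᵞ + o) + ε`, ε ~ N(0, σ_noise),
  clipped at 0. Defaults give five centres with maximum intensities
  360 / 1 200 / 3 000 / 3 700 / 14 400 and gammas 0.85–1.15 — raw ranges
  spanning two orders of magnitude, as observed across MR vendors. A
  *null-effect mode* gives every centre the identical profile; it is used
  to verify that downstream centre identification finds nothing when
  nothing was injected.
* **Composition.** 112 healthy + 106 HCM subjects over five centres
  (29/16/70/56/47), two phases per subject, fully deterministic under a
  single seed (per-subject child generators, so cohort composition
  changes do not reshuffle other subjects' data).

What passing tests on this cohort do **not** show: robustness to real
anatomical variability, partial-volume effects, bias fields, motion, or
demographic confounds (age/sex/body size are deliberately not modelled).
The generator's centre effect is monotone; centre differences that
re-order intensities (e.g. fat suppression differences) are out of scope.

## Intensity normalisation

All four methods are rank-preserving within their fitting scope; ROI
scope fits and applies each transform per ROI label and never touches
background voxels.

* **R** — `(x − min)/(max − min)`.
* **N** — `(x − mean)/sd` (population sd).
* **HM** — empirical quantile mapping: each value goes to the template
  quantile at its own mid-rank quantile, linearly interpolated between
  template order statistics. The template is a single reference subject
  (deterministically the first, by id, from the reference centre).
* **PLHM** — per training image, percentiles on the grid
  {1, 10, 20, …, 90, 99} are affinely mapped so p1/p99 hit [0, 1], then
  averaged across the reference population into standard landmarks;
  application pieces a linear map through the input's own grid
  percentiles, extrapolating linearly beyond the anchors. The p1/p99
  anchors are an addition over plain deciles for tail handling; the grid
  is configurable.

The reference centre defaults to the largest centre in the cohort.
Standard range [0, 1] keeps post-normalisation bin width 0.05 meaningful
(20–80 grey levels). Degenerate inputs (constant regions) yield zeros
(R, N) or the range midpoint (PLHM) with a warning rather than NaN, so
pipelines survive pathological synthetic ROIs.

## Feature extraction

Discretisation is fixed-bin-width, anchored at the per-ROI minimum
(min maps to level 1). Bin widths: 25 for raw images, 0.05 after
normalisation. The same level set is used for all matrix families —
per-family discretisation is deliberately not implemented.

Texture matrices (3D by default, 2D mode available):

* GLCM: co-occurrences over the 13 unique 3D directions, summed and
  symmetrised into one matrix before feature computation;
* GLRLM: maximal same-level runs per direction, summed over the 13
  directions (a direction that does not fit the volume contributes a
  length-1 run per voxel); run percentage is taken relative to the
  summed-direction voxel budget;
* GLSZM: connected same-level zones, 26-connectivity;
* GLDM: dependence counts over the 26-neighbourhood with level tolerance
  α = 0; the dependence size includes the centre voxel (j ≥ 1).

Feature panels follow the common radiomics taxonomy (18 first-order,
GLCM 24, GLRLM 16, GLSZM 16, GLDM 14 = 88 per ROI). Shape features are
excluded by design: they depend only on the segmentation. Implementation
correctness is established by equality against brute-force enumeration
oracles on hundreds of random small volumes, not by spot checks.

Feature tables use a fixed canonical column order — ROI (LV, MYO, RV),
then family (firstorder, GLCM, GLDM, GLRLM, GLSZM), then name
alphabetically. The order matters because the sequential correlation
filter is order-dependent; fixing it makes filtering deterministic.
Studies with an empty ROI are missing-coded and excluded downstream.

## ComBat harmonisation

Features are first mapped, per centre, through an empirical quantile
transform onto a standard normal (K = 20 quantile grid, linear
interpolation, average ranks on ties) because the location/scale model
assumes per-batch normality. Fitting then standardises each feature
against the grand mean and the *within-batch pooled* sd (the "virtual
reference" — no batch is privileged), estimates per-batch means and
variances of the standardised data, fits normal / inverse-gamma priors
across features by method of moments, and shrinks via the standard
iterative conditional update (tolerance 1e-4, cap 500 iterations).
Zero-variance features pass through with a warning. The implementation
is verified to match Bioconductor's `sva::ComBat` (parametric, no
covariates) to ~1e-4 on simulated batches, and to recover injected
location/scale effects.

## Variability analysis

JSD is base 2, so it lives in [0, 1] — the similarity threshold
τ = 0.01 is base-dependent and this choice is therefore part of the
method's definition here. Divergences are computed on healthy subjects
only (disease subgroups would confound centre comparison), per
(ROI, feature order, phase) group, after greedy sequential
de-correlation at R² ≥ 0.9, for all C(n_centres, 2) centre pairs.

Histograms share a support (pooled range, equal-width bins) with
additive smoothing ε = 1e-10. The bin count scales as ⌊√n_min / 4⌋ with
a floor of 2, where n_min is the smaller sample. Rationale: the
same-distribution sampling-noise floor of the JSD is ≈ (B − 1)/(5.5 n);
this rule places it near τ for cohort-typical per-centre sample sizes
(n ≈ 20–30, where the threshold then sits at the median of the observed
JSD distribution) and sends it to zero for large n, so identical
distributions register as similar while genuine location/shape shifts
(≥ 0.5 sd) almost never do. A fixed fine binning would instead put even
identical distributions far above τ at these sample sizes, voiding the
threshold. Comparisons at the threshold are strict (< τ counts as
similar).

Method comparisons use two-sided Mann–Whitney U (two groups) or
Kruskal–Wallis (three or more) at the 0.01 level with Bonferroni
correction.

## Evaluation protocols

Random forests: 500 trees, √p features per split, unlimited depth,
single-threaded, seeded — fixed rather than tuned, trading accuracy for
stable, reproducible importances. Balanced accuracy (mean per-class
recall) is the metric throughout, given class and centre imbalance.

* *Centre identification*: healthy subjects, one (order, ROI) feature
  block, stratified 5-fold CV on centre labels.
* *Generalisation*: first + second order features from all ROIs, no
  prior feature selection; per seed (5 seeds), stratified 5-fold CV
  within the training centre gives validation accuracy and each fold's
  model is scored on the pooled held-out centres (per-centre breakdown
  derivable from the fold table). Pooling is a documented choice; the
  alternative (average per centre) weighs small centres up.

Gini importances are averaged over folds and seeds; top-k listings are
annotated with ROI and family.

## Problem sizes used in the shipped checks

The test suite's end-to-end checks run the default 218-subject cohort at
the ED frame; the acceptance script runs both frames plus three
normalisation variants (ROI rescale, whole-image PLHM, ROI PLHM) and
ComBat, completing in a few minutes on one CPU. The byte-identity
determinism check uses a scaled grid (2 centres × 12 subjects, 2 slices,
25 trees): determinism does not depend on scale. ComBat recovery is
checked at 5 batches × 800 subjects × 30 features so that per-cell
variance sampling noise (≈ √(2/n)) sits well inside the asserted band.

## Known limitations

* The synthetic centre effect is voxel-wise monotone plus noise; spatial
  artefacts (bias fields, ghosting) are not modelled, so normalisations
  are compared under favourable conditions.
* PLHM assumes the input histogram's central mass is informative; it can
  distort bimodal whole-image histograms (background + tissue), which is
  precisely why ROI-level application often behaves better.
* The JSD binning rule is tuned to the two-sample setting with tens of
  observations; for very large samples a fixed-resolution comparison
  may be preferable (the bin count is an explicit parameter).
* ComBat here is the parametric, covariate-free variant; preserving
  biological covariates or non-parametric priors is out of scope.
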