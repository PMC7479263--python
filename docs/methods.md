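# Methods

This note documents the statistical procedures `rpmap` implements, the
synthetic phantom that stands in for patient data, the numerical choices,
and what the test suite does and does not establish.

## The mapping problem

Radio-pathomic mapping regresses a histology-derived scalar — the
epithelium density, an area fraction in [0, 1] — on co-registered MRI
features, then evaluates the regression voxel-wise to paint a density map
over the prostate in MRI space. The package assumes the upstream work
(acquisition, intensity normalization, histology segmentation,
MRI–pathology co-registration) is done: its inputs are per-slide rasters
already on a common grid — six feature maps (normalized T2, three ADC maps
from different b-value pairs, the b=0 image, a T1 subtraction map), a
prostate mask, a density map, and one integer annotation map per observer
over the vocabulary {unlabeled, atrophy, HGPIN, G3, G4 fused, G4
cribriform, G5}.

## Agreement analysis

Annotations are recoded to three ordinal categories: 0 unlabeled, 1 low
grade, 2 high grade (G4 and above). The published three-category scheme
does not say where benign atrophy and HGPIN fall; the defaults send
atrophy to 0 (it is benign) and HGPIN to 1 (it is a neoplastic precursor),
and both placements are configurable.

Krippendorff's α uses the coincidence-matrix formulation with the ordinal
distance δ²(c,k) = (Σ_{g=c..k} n_g − (n_c+n_k)/2)² on the coincidence
marginals; each unit with m ≥ 2 ratings contributes ordered pairs weighted
1/(m−1). The **unit is the voxel**: after co-registration the voxel grid is
the only geometry all observers share. Because agreement statistics assume
shared unit boundaries and observers draw their own, the analysis is run
once per observer, on the footprint of voxels that observer annotated;
other observers' unannotated voxels there count as rated "unlabeled" (a
category, not missing data). Confidence intervals are percentile bootstrap
over **slides**, not voxels — labels are strongly spatially correlated
within a slide, so voxel resampling would be anti-conservative. Pooling
across slides uses per-slide coincidence matrices as sufficient statistics,
which makes the 500-resample bootstrap O(1) per resample.

## Lesion tables

Lesions are 4-connected components of one label value, kept only when
**strictly larger than 200 voxels** in plane (`min_area_vox=201`). Each
kept region contributes one training row: the median of each feature and
the median density over its voxels (standard midpoint median for even
counts — this affects even-sized regions and is deliberate). Controls are
benign-atrophy regions in single-annotator datasets; in multi-annotator
datasets, where atrophy-annotation habits differ wildly, an
unlabeled-consensus control is built instead: all voxels any observer
labeled G3 or higher are subtracted from the prostate mask and the
remainder is split per slide into four equal-size regions by row-major
chunking (deterministic and reproducible; a spatially compact k-means
variant is available behind `compact=True`). Remainder voxels are dropped
and logged.

## The density model

With one latent variable, PLS regression has a closed form that coincides
with NIPALS: after centering and scaling X (features carry heterogeneous
physical units; PLS is scale-sensitive) and centering y, w = Xᵀy/‖Xᵀy‖,
t = Xw, p = Xᵀt/tᵀt, q = yᵀt/tᵀt, and the prediction folds back into an
affine map β, β₀ on raw features. Fits require more rows than features,
reject zero-variance features by name, and raise a degenerate-model error
when y has no covariance with any feature. Predictions are clipped to
[0, 1] (density is a fraction); clip counts are logged. One model is fitted
per pathologist on that pathologist's pooled lesion rows plus the shared
consensus controls; the consensus map is the voxel-wise mean of the
per-pathologist maps over the intersection of their masks.

## Evaluation statistics

The classification task is high-grade (G4+) versus low-grade (G3) plus
benign, scored by the region-median predicted density. AUC is the
Mann–Whitney statistic with ties counted ½ (identical to the area under
the empirical ROC staircase). The ADC comparator is auto-oriented: if its
raw AUC is below 0.5 the sign is flipped (lower ADC means denser tumor)
and the orientation recorded.

Two AUCs measured on the same lesions are compared with the Hanley–McNeil
z-test, z = (A₁−A₂)/√(SE₁² + SE₂² − 2r·SE₁SE₂), with
SE² = [A(1−A) + (N₁−1)(Q₁−A²) + (N₂−1)(Q₂−A²)]/(N₁N₂), Q₁ = A/(2−A),
Q₂ = 2A²/(1+A). Two printed-formula issues deserve a note. First, the
typeset source equation lacks the radical; the standard form above is
implemented, and a literal variant (no radical, Q₁ = A(2−A)) is kept
behind `roc_compare(as_printed=True)` purely for audit. Second, the Q₁
above is the correct one: under a binormal simulation (N₁=N₂=40, A≈0.77)
the Monte-Carlo SD of the AUC estimator is 0.0525 and this formula gives
0.0531, while the literal reading gives 0.103 — double — which would make
the test wildly conservative. The correlation term r defaults to the mean
of the Kendall τ between the two score vectors on the positives and on the
negatives (the input statistic of the published lookup table; a
user-supplied `r_lookup` can interpolate a table instead). This surrogate
slightly underestimates the true correlation of the two AUC estimates, so
the test runs a little conservative: measured type-I error is 0.034 at
nominal 0.05 over 2000 seeded null replicates.

Per-model means are compared with a one-way within-subject ANOVA (lesion
as subject): the per-lesion effect is removed before forming MS_error, so
F = MS_model/MS_error with df = (k−1, (k−1)(n−1)), and F is invariant to
any per-lesion constant. Tukey's HSD runs on the same within-subject error
term, q = |m_i − m_j|/√(MS_error/n), against the studentized range with
(k, df_error). Degenerate inputs are flagged rather than mis-reported: all
columns identical gives F = 0 and no significant pairs; distinct columns
with exactly zero error variance gives F = ∞ with a degeneracy flag (an
error sum of squares at the rounding level of the decomposition, ≤ 10⁻¹²
of the total, counts as zero).

Bootstrap AUC intervals are percentile over 500 lesion resamples,
stratified by class so no resample loses a class.

## The phantom

The generator emulates exactly the statistical structure the analysis
assumes, so that passing tests are informative about the pipeline, not
about prostate biology:

- **Geometry.** An elliptical gland mask on a 96×96 grid (0.5 mm²/voxel by
  default); per slide, a truncated-Poisson number (mean 4, max 5) of
  non-overlapping axis-aligned ellipses with semi-axes 6–13 voxels, placed
  largest-first by rejection sampling (bounded tries, then a hard error).
  Real lesions are freehand; geometry is irrelevant to the statistics
  tested.
- **Density.** Class-mean density increases strictly with severity
  (stroma 0.20 < atrophy 0.26 < HGPIN 0.33 < G3 0.43 < G4FG 0.53 <
  G4CG 0.59 < G5 0.68 by default; values in this range are typical of
  epithelium area fractions, and the background value is a package choice
  since no published density model exists for non-lesion tissue). On top:
  a per-lesion offset (SD 0.08) modelling lesion-level biological
  variability that ROI medians cannot average away, and a boxcar-smoothed
  voxel texture (SD 0.05) for within-region spread.
- **Features.** Each feature is an affine function of density — negative
  slopes for T2 and the three ADC maps, positive for b=0 and T1
  subtraction — plus white voxel noise (SD 0.05) and a spatially
  correlated Gaussian field (SD 0.15, correlation length 8 voxels)
  standing in for coil shading, registration residue and other structured
  artefacts. The correlated component is what keeps lesion-median features
  noisy and single-feature discrimination (ADC) imperfect, as in real
  cohorts; with white noise alone every ROI median would be essentially
  exact and all AUCs would saturate at 1.
- **Observers.** Each simulated annotator drops lesions with a per-class
  detection probability, relabels through a row-stochastic confusion
  matrix concentrated on adjacent grades (the G3/G4 boundary is where real
  pathologists disagree most), dilates or erodes outlines by a half-normal
  radius, and may decline to annotate atrophy. The five default profiles
  span these styles.
- **Seeding.** One master seed; slide content and each observer use fixed
  substream keys, so adding an observer or extending the cohort never
  perturbs existing draws.

What the phantom does **not** model: histology-resolution appearance, 3D
continuity across slides, registration error, non-monotone
feature–density relationships, and non-cancerous confounders (BPH,
prostatitis). Consequently the tests demonstrate correctness and
calibration of the statistical machinery under the stated generative
assumptions — not clinical performance.

## Study scales

The default `run_experiments` scale is 20 synthetic patients — 12 patients
(24 slides) annotated by all five simulated observers for training, 8
patients (16 slides) annotated by one observer for testing — which yields
roughly 30–45 evaluation lesions and runs in well under a minute. At that
lesion count the consensus-vs-ADC z-test is usually not significant even
though the consensus AUC is higher; the test suite demonstrates the
significance claim at a scaled-up evaluation cohort (30 test patients,
~190 lesions). The bootstrap-coverage studies use 33-slide replicates
(a realistic multi-annotator cohort size) on 48×48 grids
with proportionally smaller lesions, 200 replicates, against a reference
value computed from a 600-slide (α) or 1500-slide (AUC) run.

## Known limitations

- The r surrogate for the correlated-ROC test is conservative (see above);
  supplying a tabulated `r_lookup` removes most of the gap.
- Percentile bootstrap intervals at a few dozen resampling units cover
  slightly below nominal (92–93% measured at 95% nominal); this is a
  property of the percentile method, shared with the original analyses.
- The unlabeled-consensus construction (per-slide row-major chunking into
  four regions) is one of several defensible readings of "four equally
  sized ROIs"; the choice is isolated behind `consensus_unlabeled_rois`.
- Voxel-wise agreement units overweight large lesions relative to a
  lesion-wise reading of the agreement analysis; the sufficient-statistics
  API accepts any unit-count matrix, so a lesion-wise variant is easy to
  build externally.
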