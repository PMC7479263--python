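# rpmap — radio-pathomic mapping of prostate epithelium density

`rpmap` is a research pipeline for **radio-pathomic mapping (RPM)**:
predicting a histology-derived quantity — here the **epithelium density**,
the area fraction of epithelial cells on H&E-stained whole-mount prostate
slides, a marker of Gleason-grade severity — voxel by voxel in MRI space
from co-registered multi-contrast MRI features. It is aimed at rad-path
researchers who want to study how such maps behave when the pathology
ground truth comes from several disagreeing annotators.

The pipeline has three stages:

1. **Annotation agreement.** Multi-observer lesion annotations (benign
   atrophy, HGPIN, Gleason 3, Gleason 4 fused/cribriform, Gleason 5) are
   recoded to three ordinal categories (unlabeled / low grade / high grade)
   and inter-observer agreement is measured with ordinal **Krippendorff's
   α = 1 − D_o/D_e**, repeated once per observer's annotation footprint,
   with slide-bootstrap 95% CIs.
2. **Per-pathologist density models.** For each observer, lesion-wise
   training rows (median of each MRI feature and of the epithelium density
   over every annotated region larger than 200 voxels, plus
   unlabeled-consensus control regions) feed a **partial least squares
   regression with one latent variable**: after standardization,
   w ∝ Xᵀy, t = Xw, ŷ = ȳ + q·t. The fitted map is applied voxel-wise to
   held-out slides, and the per-model mean predictions are compared with a
   repeated-measures ANOVA plus Tukey's HSD.
3. **Consensus model vs ADC.** The per-observer maps are averaged into a
   consensus map, scored lesion-wise against the task *high-grade (G4+) vs
   low-grade (G3) / benign*, with empirical ROC curves, 500-iteration
   bootstrap AUC CIs, and the **Hanley–McNeil correlated-ROC z-test**
   z = (A₁−A₂)/√(SE₁² + SE₂² − 2r·SE₁SE₂) against the ADC feature, where r
   comes from the Kendall τ between the two score vectors on positives and
   negatives.

Because no patient data ship with the package, a **synthetic phantom**
generates pre-aligned rad-path slides: an elliptical gland mask, lesions
with severity-graded density, six MRI-like feature maps that are noisy
affine functions of density, and simulated annotators with boundary jitter,
grade confusion and per-class detection rates. Every stage of the pipeline
is exercised and tested on this phantom.

## Worked example

```python
import numpy as np
from rpmap import (PhantomConfig, generate_cohort, annotate_cohort,
                   default_annotator_profiles, extract_lesions,
                   consensus_unlabeled_rois, build_training_table,
                   fit_pls1, predict_map)
import pandas as pd

cfg = PhantomConfig(n_patients=3, slides_per_patient=2, seed=42)
slides = generate_cohort(cfg)
annotate_cohort(slides, default_annotator_profiles(5), seed=cfg.seed)

tables = []
for s in slides:
    lesions = extract_lesions(s.annotations["obs1"], s.prostate_mask,
                              slide_id=s.slide_id, observer="obs1")
    lesions += consensus_unlabeled_rois(s.annotations, s.prostate_mask,
                                        k=4, slide_id=s.slide_id)
    tables.append(build_training_table(lesions, s.features, s.truth_density))
table = pd.concat(tables, ignore_index=True)
print("training rows:", len(table))

cols = [c for c in table.columns if c.startswith("x_")]
model = fit_pls1(table[cols].to_numpy(), table["y"].to_numpy())
print("weights:", dict(zip([c[2:] for c in cols], np.round(model.w, 3))))

pred = predict_map(model, slides[0].features)
mask = slides[0].prostate_mask
rho = np.corrcoef(pred.data[mask], slides[0].truth_density.data[mask])[0, 1]
print("voxelwise corr with truth on slide 0: %.3f" % rho)
```

prints

```
training rows: 37
weights: {'T2_norm': -0.423, 'ADC_0_1000': -0.405, 'ADC_1000_2000': -0.409,
          'ADC_500_2000': -0.506, 'B0': 0.345, 'T1_sub': 0.338}
voxelwise corr with truth on slide 0: 0.888
```

The 37 rows are the observer's kept lesions plus four consensus control
regions per slide. The PLS weight vector is proportional to each feature's
covariance with density: the T2- and diffusion-derived features load
negatively (dense tumor is dark on T2 and restricts diffusion) while the
b=0 and T1-subtraction features load positively. The fitted map correlates
0.89 with the true density field on the training slide.

A `rpm` command-line tool exposes each stage (`rpm phantom`,
`rpm agreement`, `rpm build-table`, `rpm fit`, `rpm predict`,
`rpm consensus`, `rpm evaluate`) and a one-shot `rpm run-all`.

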