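# glaufuse

Structure–function data fusion for automated glaucoma diagnostics.

Glaucoma damages both visual function (measured by Standard Automated
Perimetry, SAP) and retinal structure (the peripapillary retinal nerve
fibre layer, RNFL, measured by Optical Coherence Tomography, OCT).  The two
modalities are anatomically linked: every visual-field region is served by
nerve-fibre bundles entering a particular sector of the optic disc.
`glaufuse` implements a classification pipeline that exploits this link by
*fusing* the two tests before classification, instead of leaving a
classifier to discover the relationship from limited training data:

- **Fused OCT** — each of the 256 circumpapillary A-scan thickness values
  (µm, TSNIT order) is age/refraction-corrected against a normative
  database; values below the normative 5th percentile are multiplied by
  `exp(-α · s̄)`, where `s̄` is the mean pattern-deviation probability score
  of the retinotopically corresponding visual-field sector on a six-sector
  anatomical map.
- **Fused SAP** — each of the 52 visual-field pattern-deviation scores
  receives an additive factor: the score of the most extreme
  sub-5th-percentile A-scan in the corresponding scan-circle sector (or, in
  its absence, the negative score of the most extreme supra-95th-percentile
  position, allowing attenuation).

Classification uses a bagged ensemble of 35 cascade-forward multilayer
perceptrons (two tanh hidden layers plus direct input connections to every
layer, one logistic output) trained by Møller's scaled conjugate gradient
with rotating early-stopping subsets, evaluated by stratified 10-fold
cross-validation.  Input types `SAP`, `F_SAP`, `OCT`, `F_OCT`, `SAP_OCT`
and `F_SAP_F_OCT` are compared with paired ROC statistics: AROC, DeLong's
test for correlated AROCs, McNemar's exact test on paired accuracies,
sensitivity×specificity cutoff selection, and agreement odds ratios.

Because no clinical data ship with the package, a synthetic-cohort module
generates normative and study cohorts with the statistical structure the
pipeline assumes (spatially coupled SAP/OCT defects, severity strata by
Mean Deviation); every stage is testable end to end without a download.

## Worked example

```python
import numpy as np
import glaufuse as gf
from glaufuse.ann import TrainConfig

# synthetic cohorts: a healthy normative cohort and a 125/135 study cohort
normative = gf.generate_normative_cohort(300, gf.PAPER_STUDY, seed=1)
db = gf.build_normative_db(normative)
study = gf.generate_study(gf.PAPER_STUDY, seed=1)

# combined fused input -> 10-fold CV of the 35-member ensemble
fs = gf.assemble_features(study, "F_SAP_F_OCT", norm=db)
cv = gf.crossvalidate(fs, k=10, config=TrainConfig(), seed=1)

r = gf.roc(cv.scores, cv.labels)
cut = gf.select_cutoff(r)
acc = np.mean((cv.scores >= cut).astype(int) == cv.labels)
print(f"AROC {r.auroc:.4f}  cutoff {cut:.3f}  accuracy {100*acc:.2f}%")
```

Output:

```
AROC 0.9934  cutoff 0.264  accuracy 96.54%
```

The out-of-fold AROC of 0.9934 is the probability that a randomly chosen
glaucoma record scores higher than a randomly chosen healthy one; the
cutoff maximizes sensitivity × specificity over the swept thresholds, and
the accuracy is the fraction of the 260 records classified correctly at
that cutoff.  The same objects feed the paired tests, e.g.
`gf.delong_test(cv_a.scores, cv_b.scores, labels)`.

A `glaufuse` command-line tool wraps the same steps
(`simulate`, `validate`, `build-norm`, `fuse`, `features`, `train`,
`evaluate`); see `glaufuse --help`.

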