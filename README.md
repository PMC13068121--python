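# vestlat

Lateralization of unilateral vestibular deficits from laboratory
vestibular test asymmetries.

In unilateral vestibular schwannoma the tumor suppresses vestibular
function on one side, and the clinical work-up quantifies the left-right
imbalance with a battery of tests: video head impulse testing (vHIT; VOR
gains of the six semicircular canals), cervical/ocular VEMPs
(peak-to-peak amplitudes), bithermal caloric irrigation (slow-phase
velocities) and the subjective visual vertical (SVV). `vestlat`
implements, as a tested and reusable pipeline, the regression-based
analysis that asks **which tests best predict the affected side** (known
from MRI):

- the battery's Jongkees-style asymmetry statistics, including the
  composite anterior-posterior measure
  `cmpAP = (RP·LP − RA·LA)/(RP·LP + RA·LA) · 100`,
  with a canonical sign convention (positive = right side affected);
- removal of the monocular-vHIT recording bias by subtracting a
  comparison group's normative left-minus-right gain offset;
- fold-aware cleaning of the metric table (1-nearest-neighbor
  imputation, mean ± 2 SD winsorization, range normalization or
  z-scoring — all refitted inside every cross-validation fold);
- leave-one-out cross-validated side prediction (unregularized logistic
  regression, Gaussian naive Bayes, linear SVM) with pooled-score ROC,
  bootstrap AUC confidence intervals, Youden-optimal operating points,
  SVM-weight feature ranking, stepwise multivariate AUC, canal-proxy vs
  otolith-proxy models, and paired bootstrap AUC comparisons;
- a synthetic cohort generator that emulates the statistical structure
  of such a study (lateralized deficits, right-favoring vHIT gain bias,
  per-test missingness and outliers, a configurable fraction of
  asymmetries opposing the tumor side), so the whole pipeline is
  testable end to end with known ground truth.

## Worked example

```python
import numpy as np
from vestlat import SyntheticConfig, generate_cohort, generate_controls, AffectedSideModel

cfg = SyntheticConfig(seed=42)            # 68 patients + 33 controls
patients = generate_cohort(cfg)
controls = generate_controls(cfg)

model = AffectedSideModel.from_records(patients, controls, n_boot=500)
res = model.fit(metrics=["caloric_cp", "cvemp_ar"], seed=42)
print(res.summary())
```

prints

```
Affected-side prediction (LOOCV)
============================================
classifier:        logistic
metrics:           caloric_cp, cvemp_ar
n patients:        68  (right 34 / left 34)
positive class:    +1 (right side affected)
AUC:               1.000
95% CI (bootstrap): (1.000, 1.000)  [500 resamples, seed 42]
held-out accuracy: 1.000
operating point:   sens 1.00, spec 1.00, J 1.00 @ thr 0.057
```

Every patient here is scored by a model trained on the other 67 (with
imputation, winsorization and standardization refitted per fold); the
AUC of 1.0 says the combined caloric + cVEMP asymmetry separated the
right- from left-affected patients perfectly at this seed, and the
operating point is the threshold maximizing Youden's J. Companion
analyses hang off the same model object: `model.univariate()` (per-test
AUCs — caloric/cVEMP/RLLL high, SVV low, cmpAP at chance under the
default conditions), `model.rank_features()`, `model.stepwise()`,
`model.grouped()` and `model.compare_classifiers()`;
`res.plot_roc()` draws the ROC curve.

The same pipeline runs from the shell:

```bash
vestlat simulate --seed 42 --out-patients patients.csv --out-controls controls.csv
vestlat predict --patients patients.csv --controls controls.csv --seed 42
```

and `vestlat report --config run.json` executes the full analysis
(simulate/read → bias-correct → metrics → descriptives → predict) and
writes a report bundle (metric table, descriptive summaries, pre/post
t-tests, univariate/stepwise/grouped AUCs, classifier comparison,
held-out scores, resolved configuration with hash and seed).

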