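# Methods

## Problem

A unilateral vestibular schwannoma suppresses vestibular function on the
tumor side. The clinical test battery quantifies left-right function
asymmetry through four instruments: the video head impulse test (vHIT;
one VOR gain per semicircular canal), cervical and ocular VEMPs
(peak-to-peak reflex amplitudes per side), bithermal caloric irrigation
(four maximal slow-phase velocities), and the subjective visual vertical
(six signed trial shifts in degrees). `vestlat` asks how well each
asymmetry statistic — alone and in combination — predicts the MRI-given
affected side, using leave-one-out cross-validated ROC analysis, and
provides a synthetic cohort generator so that every stage is testable
without patient data.

## Asymmetry statistics

All ratio metrics are Jongkees-style normalized differences in percent,
bounded in [-100, 100]:

| metric | definition | as-printed sign |
|---|---|---|
| RLLL | (LL − RL)/(RL + LL) · 100 | left − right |
| RALP | (LP − RA)/(RA + LP) · 100 | left − right (plane) |
| LARP | (LA − RP)/(LA + RP) · 100 | left − right (plane) |
| cmpAP | (RP·LP − RA·LA)/(RP·LP + RA·LA) · 100 | posterior − anterior products |
| VEMP AR | (R − L)/(R + L) · 100 | right − left |
| caloric CP | [(RC+RW) − (LC+LW)]/(RC+RW+LC+LW) · 100 | right − left |
| SVV shift | mean of six signed trials, degrees | rightward tilt positive |

The composite vertical measures are kept with their derivation: `cmp_b`
(the mean of the RALP and LARP fractions) equals its product expansion
(LA·LP − RA·RP)/(LA·LP + RP·LP + RA·LA + RA·RP)·100 identically, which
the test suite verifies to 1e-10; `cmp_ap` is the Jongkees ratio of the
pair products RP·LP and RA·LA.

Because the printed formulas mix left-minus-right (vHIT) and
right-minus-left (VEMP, caloric) orientations, a canonicalization layer
re-signs every metric to a single convention — **positive = right side
affected** — before any side scoring or classification. The map is
{rlll:+, ralp:+, larp:+, cmp_ap:+, ovemp_ar:−, cvemp_ar:−,
caloric_cp:−, svv_shift:+}; applying it twice is a state error, never a
silent involution. Pathological thresholds (lateral gain < 0.8, vertical
gain < 0.7, |CP| > 25 %, |SVV| > 2.2°) are strict: boundary values are
normal.

Two structural facts about the vertical-canal metrics are worth
recording. An anatomical mirror (swapping every left/right raw
measurement) maps the RALP plane onto the LARP plane, so those two
metrics negate as a pair rather than individually; and `cmp_ap` is built
from the side-symmetric products RP·LP and RA·LA, making it exactly
mirror-invariant — it measures anterior-vs-posterior, not left-vs-right,
imbalance, which is why its side-prediction AUC sits at chance.

## Monocular vHIT gain-bias correction

Right-eye monocular vHIT recording inflates right-canal gains. The
normative left-minus-right mean gain difference of a vestibularly normal
comparison group estimates this offset per canal type; it is subtracted
from patients' left gains (default), which makes corrected difference =
raw difference − offset exactly, with corrected gains floored at 0.01.
A `split` variant shares the offset half-and-half between sides; unlike
the one-sided default it commutes with a full left/right mirror of the
raw data. One-sample t-tests of the pair differences are reported before
and after correction. The offset is estimated once on the full
comparison group (never inside CV folds) because the comparison group is
never classified.

## Fold-aware preprocessing

The per-patient metric table is cleaned inside every cross-validation
fold; the model is fitted on the n−1 training rows and applied to the
held-out row, so nothing about a held-out patient reaches the fold's
statistics.

- **1-NN imputation.** A missing entry takes the value of the nearest
  training row, with Euclidean distance over mutually observed columns
  rescaled by sqrt(n_columns/n_shared); exact ties go to the smallest
  training-row position. Fitting imputes the training matrix itself with
  self-exclusion. k = 1 is fixed a priori (averaging over k > 1
  neighbors would shrink asymmetry magnitudes).
- **Winsorization.** Entries beyond the training mean ± 2 sample SD are
  replaced by the most extreme training value still inside the bound in
  that direction (falling back to the bound when none exists).
- **Range normalization** (descriptive path): division by the training
  max − min. **Standardization** (classifier path): training z-scores.
  Zero-range/zero-SD columns are dropped with a warning.

Order is fixed: impute → winsorize → normalize (descriptives) or
standardize (classifiers). Winsorization is idempotent under the same
fitted model; the rescaling steps map their own training output to
itself when refitted on it.

## Side prediction

Labels are −1 (left) / +1 (right). Under LOOCV each patient is scored by
a preprocessing model and classifier fitted on the other n−1 patients:
log-odds for unregularized logistic regression (lbfgs, max 200
iterations, tol 1e-8, scores capped at ±30 to guard exact separation),
log posterior ratio for Gaussian naive Bayes (variance floor 1e-9), or
the signed margin of a linear SVM (C = 1, fixed a priori). Because each
fold refits the classifier, raw decision values from different folds are
not on a common scale — the fold intercept and the leave-one-out
influence of the held-out point both wander with training composition,
and pooling raw values is badly anti-calibrated for weak effects (pooled
null AUCs can land near 0). Each held-out value is therefore z-scored
against its own fold's training decision values before pooling: a
monotone within-fold transform that leaves discrimination intact and
makes the pooled ROC well defined.

The pooled scores feed: a trapezoidal ROC/AUC (identical to the
Mann-Whitney pairwise-concordance probability with ties counted ½ — the
suite checks this against an exhaustive oracle to 1e-12); a 95 %
stratified percentile-bootstrap CI (2000 resamples by default, seeded);
the Youden-J optimal operating point (ties broken by higher sensitivity,
then lower threshold); an SVM-|weight| feature ranking fitted once on
the whole preprocessed cohort; a stepwise multivariate AUC trace along
that ranking, with the plateau reported as the smallest k within 0.005
of the maximum; grouped canal-proxy {RLLL, RALP, LARP} vs otolith-proxy
{cVEMP, oVEMP} models; and a paired patient-bootstrap AUC test
(two-sided, zero differences counted half on each side, single-class
resamples redrawn).

## Synthetic cohort generator

The generator emulates the statistical structure of the study
conditions at the level of derived measurements. Defaults (all
configurable):

- **vHIT gains**: affected ~ N(0.60, 0.10) lateral / N(0.55, 0.10)
  vertical; unaffected ~ N(0.95, 0.05) / N(0.90, 0.05); truncated at
  0.05. A recording bias (left-minus-right: lateral −0.06, anterior
  −0.01, posterior −0.03) inflates right gains of every subject,
  patients and controls alike — largest for laterals, negligible for
  anteriors, as in normative monocular-vHIT observations.
- **VEMPs**: one shared per-subject baseline (cVEMP ~ N(160, 40) µV,
  oVEMP ~ N(12, 4) µV); the affected-side amplitude is multiplied by
  0.4 (cVEMP) or 0.6 (oVEMP); log-normal noise sigma 0.2 per side.
- **Caloric**: one per-subject base SPV ~ Gamma(8, 2.5) °/s shared by
  both ears (amplitudes correlate strongly within a subject; independent
  per-ear bases would produce spurious canal-paresis sign flips); the
  affected ear is multiplied by 0.35; log-normal noise sigma 0.2 per
  condition.
- **SVV**: mean tilt 3° toward the affected side, per-trial SD 1.5°, on
  top of a per-subject idiosyncratic verticality bias SD 6° — the
  subject-level term dominates the tilt, keeping SVV weakly
  lateralizing (clinically: central compensation).
- **Discordance**: with probability `p_flip` = 0.05 *per test block* a
  patient's block is generated as if the tumor were on the opposite
  side while the label is unchanged, emulating asymmetries unexplained
  by the tumor (pre-existing contralateral deficits, atypical enhanced
  responses, test error — all test-specific phenomena).
- **Missingness** per block: oVEMP 4.4 %, SVV 5.8 %, caloric 7.3 %,
  cVEMP and vHIT 0 %. **Outliers**: probability 0.02 per measurement of
  a ×3 scaling (+15° for an SVV trial), exercising winsorization.

Every subject draws from an RNG stream derived from (seed, group,
index): cohorts are bit-reproducible and enlarging one never changes
earlier subjects.

Under these defaults the univariate AUC ordering reproduces the
qualitative clinical picture — caloric/cVEMP/RLLL high (≈ 0.9–1.0), SVV
low (≈ 0.6–0.75), cmpAP at chance — without claiming any real patient
distribution. What the generator does **not** model: tumor size or
location effects, age structure, inter-test correlations beyond the
shared lesion, head-velocity dependence of gains, and device-specific
artifacts; passing tests therefore demonstrate the correctness and
calibration of the pipeline, not clinical performance on real cohorts.

## Numerical and evaluation choices

- Estimator-consistency checks (offset recovery at n = 500) run with the
  outlier mechanism off, since ×3 gross outliers dominate the standard
  error of a mean; cohort-level analyses keep outliers on.
- Null calibration is assessed on univariate *feature* AUCs (the
  canonical metric as ROC score), for which (0.3, 0.7) is a ±3 SD
  Mann-Whitney band at n = 68. Model-based pooled LOOCV scores are not
  used for this check: for an exactly null feature the per-fold weight's
  sign instability makes their AUC distribution heavy-tailed toward 0
  regardless of pooling normalization — a known LOOCV pathology, not an
  implementation defect.
- Problem sizes in the test suite (cohorts of 20–68, bootstraps of
  100–2000, 200 null replicates) were chosen to keep the full suite
  around a minute while leaving every stochastic check at least 3 SE of
  headroom.
- Determinism: all randomness flows through seeded numpy Generators;
  the linear SVM uses a fixed solver seed; fixed data + fixed seed give
  byte-identical outputs (timestamps are confined to the run log).

## Known limitations

- The one-sided (left-gain) offset subtraction is asymmetric under
  mirroring; use `offset_side="split"` where that symmetry matters.
- LOOCV score pooling, even normalized, retains a mild pessimistic bias
  for weak effects; reported AUCs for near-null metrics (SVV, cmpAP)
  should be read as lower bounds on the feature's discriminability.
- The bootstrap CI is a percentile interval; no BCa correction.
- With heavy missingness the 1-NN imputer inherits the neighbor's side,
  so imputed-value errors are all-or-nothing rather than averaged — a
  deliberate consequence of k = 1.
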