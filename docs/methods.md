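# Methods

## Overview

`livernorm` studies one question: does normalizing a subject's liver FDG-PET
uptake by their *covariate-predicted* background — rather than reading the raw
SUV — improve patient-wise detection of focal liver lesions? The analysis has
four stages: (1) a cohort of subjects with blood-test/demographic covariates
and liver-masked SUV volumes; (2) sparse linear models, trained on healthy
subjects only, predicting each subject's background liver SUV mean E(Y) and
SD(Y) from covariates; (3) a per-voxel Z-score map
Z_i = (y_i − E(Y)) / SD(Y) with per-subject summary scores SUV_max and Z_max;
(4) a patient-wise ROC comparison of the two scores with DeLong's test.

## The penalized regression

The model minimizes (1/2n)‖y − β₀ − Xβ‖² + λ‖β‖₁ by cyclic coordinate descent
with soft-thresholding. Numerical conventions, all deliberate:

- **Objective scaling.** The penalty lives on the 1/(2n) scale (the glmnet
  convention), under which useful λ values for this problem are of order
  10⁻⁴–10⁻³. The equivalent penalty for the plain residual-sum-of-squares
  objective, λ·2n, is reported in every serialized model so either convention
  can be compared directly.
- **Standardization.** Predictors are centered and scaled to unit population
  SD (divisor n) internally; the response is centered through the unpenalized
  intercept. Reported coefficients are back-transformed to the original
  covariate scale; predictions through either parameterization agree to
  1e-10 (tested).
- **Convergence.** A sweep terminates when the largest absolute coefficient
  change is below 1e-7 (cap 10⁵ sweeps, which is never approached at these
  sizes); every fit carries a KKT certificate checked at 1e-6. Two edge cases
  bypass descent because the exact solution is known: λ = 0 (least squares)
  and λ ≥ λ_max = max_j |x_jᵀ y_c|/n (the zero vector). The latter also avoids
  last-ulp nonzero coefficients when λ equals λ_max exactly.
- **Path and warm starts.** 100 log-spaced penalties from λ_max down to
  10⁻³·λ_max, each fit warm-started from the previous solution.
- **λ selection.** The default is the support-size heuristic: the largest λ
  on the path whose support reaches the target (10 variables by default — a
  panel small enough for clinical routine); if no λ reaches the target, the
  closest support wins, ties toward stronger penalization. Two-fold
  cross-validation (seeded random equal split) is computed and written
  alongside for every run, but does not drive the default choice.

## The synthetic cohort

The generator stands in for a private screening cohort; its defaults are the
study conditions, chosen once:

- **Covariates** (n = 24): sex ~ Bernoulli(0.5) coded 0 = female / 1 = male;
  height and weight bivariate Gaussian with correlation 0.71; BMI computed
  exactly as weight/(height/100)²; all remaining covariates independent
  Gaussians at the cohort's marginal means/SDs. The height–weight correlation
  was calibrated once (design time) so the *computed* BMI reproduces the
  cohort's marginal moments (mean 23.86, SD 3.58 vs. 23.85/3.57) — with
  independent height and weight the BMI SD would be ~5.5. This is the one
  place the generator departs from fully independent draws; it buys both the
  exact BMI identity (realistic collinearity for the LASSO to contend with)
  and correct marginals.
- **SUV links.** True background mean = 0.82 + Σ coef·covariate + N(0, 0.1)
  over a 12-variable sparse support (sex 0.05, weight 0.0033, BMI 0.02,
  blood glucose 6e-5, triglyceride 1e-4, total cholesterol 2e-4, γ-GTP 2e-5,
  total protein 0.037, creatinine 0.017, insulin −0.003, albumin 0.025,
  cholinesterase 4e-5); true background SD = 0.228 + 0.0029·weight +
  N(0, 0.15). Both are floored at 0.05 SUV. The insulin slope is −0.003 by
  design: a per-unit slope of −3.2, as sometimes quoted for such models,
  would drive the predicted SUV negative at the cohort-mean insulin and can
  only be a units/scale artifact.
- **Volumes.** An ellipsoidal liver (semi-axes 60 × 45 × 40 mm, ≈ 4,650
  voxels) centered in a 96³ grid at PET voxel size 5.47 × 5.47 × 3.25 mm;
  in-mask voxels i.i.d. Normal(mean, SD) truncated at zero by resampling
  (negative-tail mass ~1e-7 at liver scale, so the truncation bias is
  negligible); zeros outside. Lesions are spheres of configurable radius
  (default 10 mm) and additive contrast (default 1.0 SUV), placed uniformly
  among voxels whose physical distance to the mask boundary exceeds
  radius + margin, so lesions lie fully inside the liver.
- **What the phantom does not emulate:** PET physics (scatter, partial
  volume, reconstruction correlations), spatial noise correlation, liver
  shape variability, non-liver anatomy, and covariate correlations beyond
  the height–weight–BMI identity. Passing tests therefore demonstrate the
  statistical machinery under the stated generative assumptions, not
  clinical performance.

## The pipeline

Healthy subjects are split into equal train/test halves by a seeded
permutation; abnormal subjects are appended to the evaluation side only and
can never reach training (asserted from the manifest). Training responses are
the *observed* in-mask SUV mean/SD of each training subject's volume
(population-SD convention, divisor n — at ≥ 10³ voxels the n vs. n−1
difference is far below noise), mirroring an image-derived measurement rather
than the generator's latent values. Predicted SDs are floored at 1e-6 SUV
(with a logged warning) before Z-scoring; outside-mask Z values are NaN so a
liver maximum can never leak from outside the mask. A single master seed
derives, via independent seed streams, the cohort, the split, the CV folds
and every subject's volume; the run manifest records config, derived seeds,
split membership, fitted models, the evaluation report and SHA-256 hashes of
all artifacts, and two runs with the same config are byte-identical.

## Evaluation

AUROC is the Mann–Whitney probability with midrank tie handling; the ROC
curve places one operating point per distinct score, so the trapezoidal area
equals the rank statistic exactly. DeLong's test uses per-subject placement
values (structural components), sample covariances (divisor m−1), and a
two-sided normal p-value; a degenerate zero variance with zero AUROC
difference returns p = 1 by convention. No small-sample correction is
applied — with tens of abnormal subjects the normal approximation is
adequate (its type-I error is verified by simulation in the test suite), but
with very few positives it is optimistic.

## Study configurations and problem sizes

- Model-recovery experiments use 3,872 healthy training subjects — the size
  of an equal split of a ~7,750-subject screening cohort — over 5 seeds. At
  residual SD 0.1 the blood-glucose and γ-GTP slopes contribute less than
  the noise floor σ/√n ≈ 0.0016 on the standardized scale, so those two
  variables are information-theoretically unrecoverable at this size; the
  recovery criterion is therefore evaluated as aggregate support recall.
- The detection study uses `normalization_benefit_config`: mean-model slopes
  doubled (covariate-driven spread of the true background mean ≈ 0.23 SUV,
  intercept shifted to keep the mean at ≈ 2.06) and subject-level SD noise
  shrunk to 0.02, isolating the mean-normalization effect; 1,000 healthy
  subjects split in half plus 25 abnormal subjects, one 10-mm lesion of
  1.0-SUV contrast each, 10 replicates. These sizes keep a full replicate
  under ten seconds on one core while leaving the AUROC comparison
  well-resolved.

## Known limitations

- Files mode requires complete covariates and an SUV/mask NIfTI pair per
  subject; there is no DICOM ingestion or liver segmentation (masks are
  inputs).
- The SD model shares the support-size target with the mean model; under the
  generator's weight-only SD link the selected SD support contains spurious
  small coefficients beyond weight, and the weight slope is shrunk by the
  penalty (observed ≲ 25% low at the default λ).
- Inference on individual coefficients (SEs, p-values) is out of scope, as
  are elastic-net/ridge variants and ROC confidence bands.
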