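# livernorm

Personalized normalization of liver FDG-PET uptake from blood-test data.

## The problem

On ¹⁸F-FDG PET, the standardized uptake value (SUV) of healthy liver tissue
varies considerably between people — with weight, BMI, glycemia, lipid profile
and liver-function markers. A focal lesion with moderately elevated uptake can
therefore hide inside a subject whose *background* liver uptake happens to be
high, and the classical detection statistic, the maximum SUV over the liver
(SUV_max), inherits all of that between-subject variability.

`livernorm` implements the remedy: estimate each subject's *expected*
background liver SUV mean E(Y) and standard deviation SD(Y) from routine
blood-test and demographic covariates, and replace the SUV map by a
personalized per-voxel Z-score map

    Z_i = (y_i − E(Y)) / SD(Y)

so that every liver is expressed in units of its own expected background. The
per-subject anomaly score becomes Z_max instead of SUV_max, and the two are
compared patient-wise by ROC analysis with DeLong's test for correlated AUROCs.

## The model

E(Y) and SD(Y) are fitted by L1-penalized (LASSO) linear regression on healthy
subjects only:

    min_{β₀, β}  (1/2n) ‖y − β₀ − Xβ‖²₂ + λ ‖β‖₁

where X holds 24 covariates (sex, age, height, weight, BMI, Brinkman index and
an 18-marker blood panel) and y is the subject's liver SUV mean (or SD)
measured inside an automatically segmented liver. The penalty λ is chosen on a
log-spaced path as the largest value keeping roughly 10 covariates — sparse
enough to be read off in clinical routine — with two-fold cross-validation
computed alongside. The solver is cyclic coordinate descent with
soft-thresholding, an unpenalized intercept, internally standardized
predictors and KKT optimality certificates; coefficients are reported on the
original covariate scale.

Because no public cohort of paired PET volumes and blood panels exists, the
package ships a first-class synthetic generator: covariates with realistic
screening-cohort moments (BMI computed exactly from correlated height and
weight), a sparse generative link from covariates to each subject's true
background SUV mean/SD, and 3-D liver phantoms (ellipsoidal mask, i.i.d.
truncated-Gaussian voxel noise at PET voxel geometry 5.47 × 5.47 × 3.25 mm)
with spherical focal lesions of fixed additive contrast in abnormal subjects.

## Worked example

Run the full analysis — simulate a cohort, fit healthy-only models on the
training half, Z-score every evaluation subject, compare Z_max with SUV_max —
in the regime where background uptake varies strongly with covariates:

```python
from livernorm import PipelineConfig, run_pipeline
from livernorm.synthetic import normalization_benefit_config, LesionSpec

config = PipelineConfig(
    cohort=normalization_benefit_config(n_subjects=1025, abnormal_fraction=25 / 1025),
    lesion=LesionSpec(n_lesions=1, radius_mm=10.0, contrast=1.0),
    seed=0,
    output_dir="example_run",
)
manifest = run_pipeline(config)

report = manifest["report"]
print(f"train/test/abnormal: {manifest['n_train']}/{manifest['n_test']}/{manifest['n_abnormal']}")
print(f"SUV-mean model support: {sorted(k for k, v in manifest['models']['mean']['coefficients'].items() if v)}")
sd = manifest["models"]["sd"]
print(f"SUV-SD model: intercept {sd['intercept']:.3f}, weight slope {sd['coefficients']['weight']:.5f}")
print(f"AUROC(Z_max) = {report['auroc_z']:.3f}   AUROC(SUV_max) = {report['auroc_suv']:.3f}")
print(f"DeLong: delta = {report['delta']:.3f}, p = {report['p_value']:.2g}")
```

which prints:

```
train/test/abnormal: 500/500/25
SUV-mean model support: ['albumin', 'bmi', 'creatinine', 'gamma_gtp', 'insulin',
 'sex', 'total_cholesterol', 'total_protein', 'triglyceride', 'weight']
SUV-SD model: intercept 0.191, weight slope 0.00274
AUROC(Z_max) = 0.886   AUROC(SUV_max) = 0.600
DeLong: delta = 0.286, p = 1.4e-07
```

Reading: the support-targeted penalty keeps 10 covariates for the mean model;
the SD model is dominated by weight, as expected. Normalizing each liver by
its covariate-predicted background lifts the patient-wise AUROC from 0.600
(raw SUV_max, confounded by between-subject background spread) to 0.886
(Z_max); DeLong's correlated-AUROC test rejects equality. The output directory
holds the covariate CSV, fitted models (JSON), per-subject score TSV, ROC
curves, and a manifest with SHA-256 hashes sufficient to re-run
bit-identically from the single seed.

The same pipeline is available from the shell:

```sh
livernorm run --n-subjects 1025 --abnormal-fraction 0.0244 --seed 0 --out example_run
livernorm simulate --n-subjects 100 --seed 1 --out sim --save-volumes 5   # NIfTI output
livernorm evaluate --scores example_run/scores.tsv
```

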