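# thymoshape

Quantitative 3D shape analysis of segmented tumors, and the statistical
pipeline that turns those shapes into a pre-operative classifier.

The motivating clinical problem is distinguishing **encapsulated** from
**invasive thymomas** (Masaoka-Koga stage I vs ≥ II) on chest CT before
surgery: invasive tumors tend to have lobulated, irregular contours,
but visual contour assessment is subjective. `thymoshape` computes
reproducible 3D shape descriptors from a binary segmentation mask and
runs the full discrimination analysis — univariate screening,
backward-stepwise logistic regression, leave-one-out cross-validation,
ROC comparison, inter-rater agreement and the associated sample-size
calculation. It is aimed at radiomics researchers who have segmentation
masks (NIfTI/NRRD) and a per-subject covariate table (CSV), and at
anyone who wants a tested, scriptable reference implementation of these
standard components.

## Shape features

For a mask with `n` foreground voxels, voxel volume `v` and physical
spacing attached:

| Feature | Definition |
|---|---|
| volume, log-volume | `V = n·v` (mL); `ln V` (log-volume is approximately normal across tumors) |
| surface area | area `A` (cm²) of the 0.5 iso-surface triangulation in physical coordinates (a light Gaussian pre-filter removes the voxelization staircase); exposed-face area available as an option |
| sphericity | `Ψ = π^(1/3) (6V)^(2/3) / A` — 1 for a ball |
| discrete compactness | Bribiesca compactness `C_d = A_c / A_c,max` with `A_c = (6n − exposed faces)/2` shared unit faces and `A_c,max = 3(n − n^(2/3))` — 1 for a solid cube, lower for lobulated objects |
| 3D roundness | `d_eq / d_max`, the equivalent-volume-sphere diameter over the maximum Feret (caliper) diameter |

Sphericity, compactness and roundness are dimensionless and
scale-invariant. Anisotropic masks are resampled to cubic voxels before
the compactness count (it is defined on unit cubes); everything else
uses physical spacing directly.

## Statistical pipeline

Covariates are screened one at a time (Pearson chi-square or Fisher's
exact test for binary factors by the expected-count-5 rule; pooled
t-test for continuous ones). Variables with screen `p < 0.1` enter
three logistic models — clinical + CT features, shape features, and
their combination — each reduced by backward stepwise selection
(likelihood-ratio removal at `p > 0.10`, re-entry at `p < 0.05`), with
VIF collinearity checks. Every subject is then scored out-of-fold by
leave-one-out cross-validation, the three ROC curves are computed
(Mann-Whitney AUC), and AUCs are compared pairwise with the DeLong test
for correlated curves. Inter-rater reproducibility of the features is
quantified by the two-way random-effects absolute-agreement ICC, with
the rater-study size given by the Fisher-z sample-size formula.

Because the original CT cohort is not public, the package ships a
synthetic layer: digital phantoms with controllable surface lobulation
(standing in for segmented tumors) and simulated 53-subject cohorts
whose per-class prevalences and feature means/SDs default to the
published summary tables.

## Worked example

```python
from dataclasses import replace
from thymoshape import (PhantomSpec, make_phantom, extract_features,
                        simulate_cohort, DEFAULT_COHORT_SPEC,
                        AnalysisConfig, run_analysis)

# a lobulated digital tumor, 12-voxel base radius
mask = make_phantom(PhantomSpec(kind="lobulated", radius=12,
                                n_lobes=6, amplitude=0.7, seed=42))
print(extract_features(mask).as_dict())
# {'volume_ml': 5.044, 'log_volume': 1.618, 'surface_area_cm2': 14.933,
#  'sphericity': 0.952, 'discrete_compactness': 0.982,
#  'roundness': 0.792, 'n_voxels': 5044}

# a simulated 23 + 30 cohort with the published class parameters
cohort = simulate_cohort(replace(DEFAULT_COHORT_SPEC, seed=7))
report = run_analysis(cohort, AnalysisConfig(seed=7))
for name, m in report["models"].items():
    print(name, m["selected"], round(m["auc"], 3))
# clinical_ct ['cystic_change', 'calcification', 'diameter'] 0.764
# shape       ['log_volume', 'discrete_compactness']         0.712
# combined    ['cystic_change', 'diameter', 'log_volume',
#              'discrete_compactness']                        0.855
```

The numbers read as in the clinical study: cystic change and discrete
compactness survive the stepwise reduction, and adding the shape
features to the clinical model raises the LOOCV AUC (here 0.764 →
0.855; the DeLong comparison for this single draw has p ≈ 0.11 at
n = 53).

The same stages are available from the shell:

```bash
thymoshape simulate-cohort --out cohort.csv --seed 7
thymoshape analyze cohort.csv --out report --seed 7   # report.json / report.md
thymoshape simulate-masks --outdir masks/ --n-enc 3 --n-inv 3 --seed 1
thymoshape features masks/*.nii.gz --out features.csv
thymoshape icc features_readerA.csv features_readerB.csv
thymoshape samplesize --rho0 0.6 --alpha 0.05 --power 0.8   # -> 16
```

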