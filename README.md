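# locrad

Local first-order radiomics with a filtered SVM workflow for classifying
prostate lesions on high b-value diffusion-weighted MRI.

Distinguishing clinically significant prostate cancer (csPCa, Gleason score
>= 3+4) from non-significant cancer (ncsPCa, GS = 3+3) before biopsy is a
standing problem in prostate MRI: the two overlap broadly in ordinary
intensity statistics, and over-calling ncsPCa drives overtreatment. This
package implements a quantitative pipeline built on *local* first-order
texture: for every lesion voxel it computes seven first-order statistics
(mean, median, skewness, kurtosis, IQR, coefficient of variation, entropy)
over a ~1 cm² patch centered on that voxel, then condenses each of the seven
per-voxel maps into twelve global summaries — 84 features per patient such
as m_σ (SD of the local-mean map, a heterogeneity measure) and s_M90th
(median of the top decile of local skewness, an asymmetry measure).

A sparse selection chain (LASSO ranking → |Pearson ρ| < 0.15 redundancy
filter → Wilcoxon rank-sum with Holm–Bonferroni correction) reduces the 84
features to a single maximally discriminant, uncorrelated couple. A linear
SVM on that couple is tuned by repeated stratified 3-fold cross-validation
with class-prior cost weighting, passed through an overfitting filter
cascade (validation AUC must not exceed training AUC; C >= 1; training
F2 >= 0.80), and calibrated with a binomial logit into a per-patient
radiomic probability score. Evaluation reports ROC/AUC with bootstrap CIs,
sensitivity/specificity/informedness at the Youden cutoff, PPV, FDR and F2.

Because cohorts of this kind are not publicly deposited, the package ships
a first-class synthetic module: phantom cohorts with elliptical multi-slice
lesions whose classes differ only in planted local-mean heterogeneity and
noise asymmetry, with per-lesion ground truth recorded so that the full
pipeline can be tested for parameter recovery end to end. See
`docs/methods.md` for the model, estimator conventions and the generator's
design rationale.

## Worked example

Run the full study — generate a 26 ncsPCa + 50 csPCa phantom cohort,
extract 84 features per patient, select a couple, train and filter the SVM,
and evaluate on the 8 + 20 holdout set:

```python
from locrad.pipeline import RunConfig, run_study

result = run_study(RunConfig(seed=1, n_reps=10, n_boot=1000))
print(result.selection.selected_couple)
print(round(result.report_test.auc, 3), result.report_test.metrics.to_dict())
```

```
('M_CV', 's_M90th')
1.0 {'sensitivity': 1.0, 'specificity': 1.0, 'informedness': 1.0,
     'ppv': 1.0, 'fdr': 0.0, 'f2': 1.0}
```

The selected couple pairs one heterogeneity-responsive feature (`M_CV`, the
coefficient of variation of the local-median map) with one asymmetry feature
(`s_M90th`); at the default strong planted effects the holdout set separates
completely, and the training set nearly so (AUC 0.994). Zero-effect cohorts
(`heterogeneity_effect=0, asymmetry_effect=0`) end with an expected-null
abort at the couple-selection stage or a chance-level AUC.

The same workflow is available from the shell, stage by stage or in one
command writing every intermediate artifact (manifest, features.csv,
selection.json, model.json, reports, provenance):

```sh
locrad run --config run.yaml --outdir run/
locrad simulate --out cohort/ --n-ncs 26 --n-cs 50 --seed 1
locrad extract --manifest cohort/manifest.csv --out features.csv
```

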