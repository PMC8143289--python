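# Methods

`locrad` implements a radiomic classification workflow for distinguishing
clinically significant from non-significant prostate lesions on high b-value
diffusion-weighted MRI (or, equivalently, on ADC maps sharing the same
geometry). The pipeline has four stages — local first-order feature
extraction, feature-couple selection, a filtered repeated-CV linear SVM, and
ROC/Youden evaluation — plus a synthetic phantom generator that provides the
statistical ground truth the real cohort cannot (patient data of this kind
are never public).

## Local first-order features

For every lesion voxel, seven first-order statistics are computed over a
square in-slice patch centered on that voxel: mean, median, skewness,
kurtosis, interquartile range, coefficient of variation, and entropy. The
patch side is derived from the in-plane pixel spacing so the window reaches
at least 5 mm from the central pixel along rows and columns:

    side = 2 * floor(5 mm / spacing) + 1, clamped to >= 3

which yields sides 7 and 5 at the protocol spacing extremes of 1.41 and
1.67 mm (a patch of roughly 1 cm^2, the smallest tissue unit considered
informative). The floor rule is a deliberate choice: a ceiling rule would
give a 9-pixel window at 1.41 mm spacing, outside the 5–7 pixel range the
acquisition supports. Patches are two-dimensional because 3 mm slices with a
3 mm gap make through-plane neighborhoods severely anisotropic; they are
truncated at image borders and deliberately *not* masked — surrounding
context pixels carry part of the local texture signal.

Estimator conventions (the names alone do not pin these down, so they are
fixed here): percentiles use linear interpolation; skewness is the
bias-uncorrected Fisher–Pearson g1 and kurtosis the excess g2; CV is the
population standard deviation over the mean; entropy is Shannon entropy in
bits over a 16-bin histogram spanning the sample's own min–max range.
Zero-variance samples set skewness, kurtosis, CV and entropy to 0 by
convention; a zero mean with nonzero spread reports CV = 0 with a logged
warning rather than an infinity.

Each of the seven per-voxel maps, pooled over all lesion voxels of all
slices (and all lesions) of a patient, is summarized by twelve global
statistics: the same seven, plus the maximum, population SD, median absolute
deviation, and the mean and median of the last decile (values at or above
the empirical 90th percentile). This yields 84 named features per patient,
`<local>_<global>`, e.g. `m_sigma` (SD of the local-mean map), `s_M90th`
(median of the last decile of local skewness), `M_CV`, `k_iqr`. Pooling to
one vector per patient (rather than per slice or per lesion) matches the
per-patient labels the classifier is trained on.

## Feature-couple selection

All selection steps see training rows only. Features are min–max scaled to
[0, 1] and then z-scored (sample SD, ddof = 1); constant features are
dropped with a warning. An L1-penalized logistic regression over 100
log-spaced penalties (from the smallest all-zero penalty down by 1e-4)
ranks features by absolute coefficient at the minimum mean cross-validated
deviance (10 stratified folds, seeded). From the LASSO-retained features,
all pairs with |Pearson rho| < 0.15 on training rows become candidate
couples: the final model deliberately uses exactly two non-redundant
features to keep 48 training patients from overfitting.

Each candidate feature gets a two-sided Wilcoxon rank-sum p-value between
classes (exact permutation null when the smaller group has <= 10 members
and the data are tie-free; otherwise the normal approximation with tie and
continuity corrections). A couple's p-value is the *larger* of its members'
— both features must discriminate — and Holm–Bonferroni step-down over the
candidate couples controls the family-wise error (rank-i threshold
alpha/(m-i+1)). The significant couple with the smallest p-value is
selected; ties break by larger summed |LASSO coefficient|, then name order.

## SVM workflow

The train/holdout split itself is model-driven: a preliminary class-weighted
linear SVM (C = 1) on the standardized full cohort ranks patients by
distance to the separating hyperplane, and the closest (support-vector
candidates) per class — 18 non-significant + 30 significant by default —
form the training set; the remaining 8 + 20 are the holdout set.

The two selected features feed a linear SVM tuned by 3-fold stratified CV
(each fold 6 + 10), re-randomized over repetitions (100 by default). The
grid spans C in 10^-2..10^3 (13 log steps) and a kernel scale gamma in
10^-1..10^1 (9 log steps), applied as input scaling x/gamma; the per-class
cost is C times the class prior of the training set. For a linear kernel,
(C, gamma) pairs with equal C/gamma^2 define the same decision rule, so grid
ties on validation F2 are pervasive; ties prefer the larger global cost
(then the smaller kernel scale), consistent with the later filter that
distrusts very low C, and fits are cached per effective cost.

Each repetition's winner (by mean validation F2; F-beta with beta = 2
weights recall four times precision, reflecting the cost of missing a
significant cancer) is refit on the full training set and passes a filter
cascade: drop models whose validation AUC exceeds their training AUC
(overfit-prone), drop C < 1, drop training F2 < 0.80; the survivor with the
highest validation F2 wins (ties: higher training F2, then smaller C). A
binomial-logit (Platt-style) calibration fitted on training decision values
maps the SVM output to the radiomic probability score in (0, 1).

## Evaluation

ROC points are computed over every threshold (no interior-point dropping)
with AUC equal to the tie-aware Mann–Whitney statistic. Sensitivity,
specificity and informedness I = SE + SP - 1 are read at the Youden cutoff
(maximum J; ties resolve toward higher specificity, reflecting the
overtreatment concern, then toward the higher threshold). PPV, FDR = 1 - PPV
and F2 are computed in exact rational arithmetic, with undefined metrics
flagged as missing rather than silently zeroed. AUC confidence intervals
use a stratified percentile bootstrap (2000 resamples, seeded) — the
interval construction is otherwise underdetermined. Group separation is
reported as the two score medians plus the rank-sum p-value; waterfall and
boxplot data (and optional PNGs) serialize with the JSON report.

## Synthetic phantom cohorts

The generator emulates the cohort geometry of the target acquisition:
in-plane spacing 1.5 mm by default (protocol range [1.41, 1.67]), 3 mm
slices, per-slice elliptical ROIs (semi-axes 4–9 mm) spanning 3–6 slices
and shrinking toward the lesion's first/last slice. Both classes share a
constant baseline signal (100 a.u., Gaussian noise SD 15); class information
lives entirely in lesion *texture*:

* **Heterogeneity** — significant lesions add a smooth random mean field
  (white noise low-pass filtered at a ~5 mm correlation length, so the
  structure survives averaging over the ~1 cm patch) with SD
  `heterogeneity_effect` (default 30 a.u.).
* **Asymmetry** — their voxel noise is right-skewed (shifted log-normal,
  zero mean, SD = `noise_sd`) with skewness `asymmetry_effect` (default 1.5).

Effect sizes in raw signal units are free parameters (no published
reference exists); the defaults are sized so each mechanism separates the
classes strongly at n = 26 + 50, the regime the workflow is designed for.

One further property is required of the generator and deserves emphasis.
The workflow selects a feature couple that is simultaneously (a) essentially
uncorrelated across patients (|rho| < 0.15) and (b) jointly highly
discriminant. If the two planted mechanisms were independent within the
significant class, these goals would be mutually exclusive: two features
with between-class shifts d1, d2 acquire a label-induced pooled correlation
of about d1*d2*p(1-p) / sqrt((1+d1^2 p(1-p))(1+d2^2 p(1-p))), which already
exceeds 0.15 for shifts big enough to matter. The resolution — and the
structure implied by the analysis this package implements — is a
within-class trade-off: each significant lesion draws a uniform phenotype
variate that splits the effect budget between heterogeneity and asymmetry
(`phenotype_tradeoff`, default 1; class means equal the configured
effects). The anti-correlated within-class responses cancel the
label-induced term in the pooled correlation while the *sum* of the two
features separates the classes almost noiselessly. Setting
`phenotype_tradeoff = 0` plants identical effects in every lesion.

The generator also records the planted per-lesion magnitudes, giving the
recovery tests ground truth: a selected couple "recovers" the mechanisms
when each member shows a significant Spearman association with the planted
magnitude across significant lesions and the two members tag different
mechanisms by the association's sign. Name-exact recovery would be
ill-posed: several of the 84 features are near-duplicates of the canonical
drivers (the spreads of the local-mean, local-median and local-CV maps all
track the heterogeneity field).

What the phantoms do *not* model: MR physics (k-space, Rician noise, T2
shine-through), anatomy-realistic prostate shapes and zonal structure,
scanner/protocol heterogeneity, segmentation variability, and multi-lesion
patients (one lesion per phantom; the extractor's pooling rule is the only
multi-lesion machinery). A pipeline that passes the recovery tests is
therefore shown to detect the intended *statistical* structure at the
stated sample sizes — not to reproduce the published patient-data AUCs,
which the acceptance preamble of the project treats as out of reach by
design.

## Determinism and problem sizes

A single master seed fans out via `numpy.random.SeedSequence` spawning to
the cohort stream (one substream per patient), the LASSO folds, the CV
repetitions and the bootstrap, so one integer reproduces a run bit-exactly;
liblinear's internal shuffling is pinned. Reported runs and the recovery
tests use 10 CV repetitions rather than 100 — with only 117 grid points on
effectively one hyperparameter ray, additional repetitions change the
survivor rarely — and 300–1000 bootstrap resamples; the defaults remain
100 and 2000.

## Known limitations

* The minimum-CV-deviance rule for the LASSO penalty is kept as specified;
  it is known to overselect on flat deviance curves, so label-independent
  features occasionally survive with small coefficients (measured: a
  designated noise feature is zeroed in ~80% of all-noise cohorts). The
  couple-level rank-sum/Holm stage is what actually controls false
  selections downstream.
* The SV-candidate split consults the whole cohort (that is its published
  definition), so the holdout set is not a fully independent draw; all
  later stages touch training rows only (property-tested).
* With a linear kernel the (C, gamma) grid is a one-parameter family in
  disguise; the kernel-scale axis matters only through C/gamma^2.
* Bootstrap percentile intervals undercover slightly at AUC near 1 and for
  8-patient groups.
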