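# Methods

`msirad` reimplements, end to end, a CT-radiomics procedure for predicting
MSI-H/MMRd status in pancreatic ductal adenocarcinoma (PDAC): 254 texture
features per region (tumor, surrounding pancreas), univariate screening,
in-fold mRMR + forward selection, four classifier back-ends, logistic fusion
of the two regions' probability scores, and repeated stratified 3-fold
cross-validation. The original patient CT scans are not publicly available,
so the package ships a synthetic phantom generator that reproduces the cohort
design and plants a controllable class-conditional texture signal; all
quantitative claims made by the test suite and the acceptance script are
about this phantom setting.

## Feature registry

Each region of each case is summarized by 254 features, computed on every
eligible axial slice (at least 16 in-mask pixels; the floor is configurable)
and averaged, unweighted, over slices. Directional matrix families are
averaged over the four planar directions (0°, 45°, 90°, 135°) before the
slice average. The layout:

| family | count | parameterization |
|---|---|---|
| GLCM | 52 | 13 Haralick statistics × pixel distances {1,2,3,4}, direction-averaged, 32 gray levels |
| HIST | 14 | mean, sd, skewness, excess kurtosis, median, min, max, range, energy, 32-bin entropy, percentiles 10/25/75/90 |
| RLM | 44 | 11 run-length statistics × quantization depths {8,16,32,64}, direction-averaged |
| FD | 48 | box-counting dimension of the thresholded set, of its inner boundary, and lacunarity × 16 thresholds |
| LBP | 72 | rotation-invariant uniform histograms for (P,R) ∈ {(8,1),(16,2),(24,3)} (10+18+26 bins) + 6 summaries each |
| ACM | 24 | 6 co-occurrence statistics × offsets {(0,1),(1,0)} × magnitude thresholds {25th, 50th pct} |

The layout is the smallest natural composition that totals 254 while making
the per-family indices cited in downstream reporting (e.g. FD48, RLM11,
LBP72) well defined; it is a reconstruction, and the name `FD31` here is a
positional convention, not an identity with any particular published feature.
The registry (version-stamped) is serialized next to every feature table.

Numerical conventions, chosen once and fixed:

* **Quantization** — 32 equal-width bins between the per-slice in-mask min
  and max (a constant region maps to level 0). Per-slice normalization makes
  the matrix features independent of the display/contrast window; histogram
  features intentionally keep raw intensity units. No HU clipping window is
  applied; phantoms are generated in arbitrary units.
* **GLCM** — symmetric accumulation (each pair counted both ways) over pairs
  whose *both* pixels are in-mask; entropies in bits with 0·log 0 := 0;
  correlation and the information measures fall back to 0 on degenerate
  marginals. Sum variance is centered on the sum average.
* **RLM** — runs are maximal in-mask collinear constant-level segments; gray
  levels are 1-based inside the low/high gray-level emphasis statistics.
* **FD** — box grids (sizes 1–16) are anchored at the mask bounding box,
  which makes the estimators exactly translation-invariant; dimensions are
  the negated log–log regression slope clipped to [0, 2]; lacunarity is the
  coefficient of variation of box masses at box size 4. An empty thresholded
  set contributes 0 for all three estimators (logged).
* **LBP** — `neighbor ≥ center` comparison with bilinear interpolation
  (scikit-image, `uniform` method). Only pixels surviving erosion of the
  mask by a disk of radius R+2 are histogrammed: interpolation at radius R
  touches grid points up to ≈ R+√2 away, so this guarantees the code depends
  only on in-mask intensities (and yields exact translation and
  intensity-offset invariance). A configuration whose eroded mask is empty is
  skipped on that slice.
* **ACM** — 3×3 Sobel gradients; orientation mod 180° in 8 bins; pixels need
  a fully in-mask 3×3 neighborhood and gradient magnitude strictly above the
  percentile threshold; a threshold/offset with no valid pair contributes six
  zeros (logged).
* A feature whose precondition fails on every eligible slice of a case is
  reported as 0 with a warning rather than NaN, so downstream tables are
  always finite; this occurs only for tiny regions (e.g. LBP at R=3 on a
  region thinner than ~10 pixels).

## Screening and selection

Screening is descriptive: each feature is tested against MSI status with a
two-sided Wilcoxon rank-sum test, exact when both groups have ≤ 10 members
and the feature is tie-free, tie-corrected normal approximation otherwise;
no multiple-testing correction (the per-region significant counts at
α = 0.05 are reported as-is). Screening does not gate the modeling path
(`screen_as_prefilter` stays off by default): selection inside each CV fold
is mRMR followed by forward selection, on training data only.

Mutual information uses equal-frequency discretization into 4 bins —
rank-invariant under strictly monotone transforms and robust at the ~63
training cases per fold — in bits, plug-in estimate. Variables that are
already discrete (the binary label) enter as-is; a continuous second variable
(feature–feature redundancy) is discretized the same way, otherwise the
redundancy term saturates near the entropy of the binned first variable and
the MID objective degenerates.

mRMR uses the MID (difference) scheme: the first pick maximizes MI(f, y),
each later pick maximizes MI(f, y) − mean MI(f, s) over already-selected s;
exact ties break toward the earlier registry index. Forward selection then
walks the mRMR order (default 15 candidates), keeping a candidate when it
improves the pooled out-of-fold AUC of an inner stratified 3-fold on the
training cases by more than 1e-3, stopping at 10 features; the first
candidate is always kept. The cap reflects the small positive class (19
cases); cap and threshold are config fields.

## Models and fusion

Four back-ends, hyperparameters fixed in config (no tuning is performed, and
the values are recorded in every report):

* logistic regression — L2, C = 1, standardized inputs;
* SVM — RBF kernel, C = 1, gamma = 1/(n_features · var), standardized
  inputs, probabilities by Platt (sigmoid) scaling fitted on the training
  fold via cross-validated calibration;
* random forest — 500 trees, √p features per split;
* XGBoost — 200 rounds, depth 3, learning rate 0.1, no early stopping.

The 1:4 class imbalance is handled with inverse-prevalence class weights in
all four kinds (resampling would disturb the stratified fold counts). Every
model emits a risk score in [0, 1].

The combined model (IntRad) is a two-input logistic regression (plus
intercept) over the tumor-model and pancreas-model scores. To keep it
leak-free it is trained on out-of-fold channel scores from an inner
stratified 3-fold on the training cases; the region models are then refit on
the full training fold and the fused test score is the combiner applied to
the two test-fold channel scores.

A caveat on tree invariance: scores of tree ensembles are invariant under
strictly monotone transforms of a feature only when every scored row is in
each tree's training sample. With bootstrapping, a point absent from a
tree's sample can fall between the adjacent sample values of a split, and
midpoint thresholds are not equivariant under the transform — so the
bootstrapped forest is only approximately rank-invariant; the property is
tested exactly for XGBoost and for the forest with bootstrapping disabled.

## Cross-validation and reporting

Repeated stratified 3-fold cross-validation, default 100 repetitions (the
test and acceptance profile uses 10 to stay desk-scale; the repetition count
is a config field). Folds are class-wise shuffled round-robin, so per-class
fold sizes differ by at most one (19 positives → 7/6/6). All repetition,
fold and inner seeds are derived deterministically from one master seed;
rerunning with the same seed reproduces the result bitwise. A degenerate
fold (single-class) triggers a reseeded repartition, at most 5 times.

Per repetition, metrics are computed on the pooled out-of-fold scores (not
per-fold then averaged — more stable with 19 positives split across 3
folds): rank-based AUC with midrank ties; the Youden threshold (maximizing
sensitivity + specificity − 1 over midpoints of adjacent distinct scores,
ties toward higher specificity, predicted positive at score ≥ threshold —
note that for anti-discriminating score sets every midpoint can have J < 0,
below the trivial all-positive/all-negative rules' J = 0; the midpoint
convention is kept because the dichotomization is only meaningful when the
score ranks positives upward at all);
sensitivity, specificity, PPV, NPV (zero-denominator predictive values are
reported missing, not 0); and the discrimination slope (mean positive score
− mean negative score). The Youden threshold is refit per repetition on the
same pooled scores it evaluates; the resulting optimism is documented here
rather than corrected. The report carries the mean of each per-repetition
metric with a 95% interval from the 2.5/97.5 percentiles across repetitions
(no distributional assumption). Decision curves use
NB(t) = TP/n − FP/n · t/(1−t) on a 0.01–0.99 grid against treat-all and
treat-none references. Feature stability is reported as the fraction of
(repetition × fold) fits selecting each feature, with the > 70% set
highlighted.

## Synthetic phantoms

A phantom is a pancreas ellipsoid (default semi-axes 24×18×5 voxels) at base
intensity 100 containing a concentric tumor ellipsoid (10×8×3) offset by
−20, in a 64×64×12 volume (~2.5 mm pseudo-spacing), over a background with
mild global Gaussian noise (sd 2). Texture is an independent 2D stationary
Gaussian random field per axial slice per region — white noise convolved
with a Gaussian kernel of width `corr_length`, recentred and rescaled to
`sigma` — added inside the tumor and the pancreas-minus-tumor shell. The
class signal is planted as a heterogeneity difference, not a mean shift:
positives receive (sigma 30, correlation length 1.5) in the configured
effect regions versus (10, 3.0) for controls and unaffected regions. These
amplitudes are placeholders — the source imaging protocol reports no
intensity statistics — and are config fields, not claims of realism. The
default cohort is 19 positives vs 76 controls (the 1:4 study design);
per-case seeds derive from the master seed by case index.

What the phantoms deliberately do not emulate: CT physics and HU
calibration, contrast kinetics, anatomy, resampling to uniform spacing, and
segmentation error. Passing the null-calibration and signal-recovery tests
therefore shows that the pipeline is leak-free and can recover a planted
texture effect of this kind at this cohort size — not that the published
patient-level performance is reproduced.

## Design choices on genuinely open points

* No canonical listing of the original 254-feature inventory is public; the registry above is an explicit reconstruction
  (config-overridable, version-stamped in outputs).
* The direction-handling that reconciles a 52/44-entry GLCM/RLM layout with
  direction-averaging: GLCM varies pixel distance, RLM varies quantization
  depth, and both average over the four directions.
* Whether the Wilcoxon screen pre-filters the selection path is ambiguous in
  the original study's description; it is treated as descriptive (flag available).
* Whether the Youden threshold was fit once globally or per repetition is
  unstated; it is refit per repetition here.
* 95% intervals are percentile-based across repetitions (the original study names
  no interval method).
* Classifier hyperparameters and the SVM probability mechanism are not
  specified in the original study; the defaults above are declared, not inferred.

## Problem sizes and limitations

The test suite and `scripts/acceptance.py` run the full pipeline on 95-case
phantom cohorts (64×64×12 voxels) with 10 CV repetitions and the
logistic-regression back-end — the package's desk-scale profile; the
defaults (100 repetitions, any of the four back-ends) are a config change.
Known limitations: no volumetric (3D) texture matrices, no wavelet/filtered
images, no shape features, no DICOM ingestion or resampling, no
hyperparameter tuning, and no external-validation logic. The published
patient-level AUCs cannot be checked against this package because the
underlying scans are available only on request from their authors.
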