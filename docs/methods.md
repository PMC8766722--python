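# Methods

## Problem setting

The pipeline targets the two-group diagnostic setting of small clinical
neuroimaging studies: a few tens of subjects, balanced AD/CN groups, and
per-modality ROI feature families (morphometry, amyloid SUVR, diffusion
FA/MD) whose dimensionality far exceeds the sample size. Everything
downstream of image preprocessing is in scope: feature selection,
per-modality classification, late fusion, and external validation.
Image handling (segmentation, registration, atlas geometry, SUV
normalization, tensor fitting) is explicitly out of scope; the pipeline
starts from subjects × named-features tables.

## Synthetic cohort model

Features follow a Gaussian linear factor model. For subject *i*, feature
*j* of modality *m*:

    x_ij = d_m · g_i · inf_j  +  λ_m · L_i · inf_j
         + √ρ_m · B_{i, b(j)} +  √(1 − λ_m²·inf_j − ρ_m) · ε_ij

with `g_i ∈ {0, 1}` the diagnosis, `inf_j` the planted-informative flag,
`L_i ~ N(0,1)` a per-subject latent factor shared by all modalities,
`B` independent per-block factors and `ε` white noise. Coefficients make
every feature's within-group variance exactly 1, so `d_m` is a
standardized effect size (Cohen's d) and every moment used in tests has
a closed form. Two useful ones:

* within-block nuisance correlation = ρ_m;
* pooled cross-modality correlation of informative features
  = (λ_a λ_b + d_a d_b / 4) / √((1 + d_a²/4)(1 + d_b²/4)) — note the
  group effect itself induces pooled correlation even at λ = 0, which is
  why "independent modalities" in tests means λ = 0 *and* correlations
  are assessed accordingly.

The constraint λ_m² + ρ_m ≤ 1 is enforced at configuration time; it is
required for the unit-variance noise decomposition to exist.

Defaults emulate a three-modality study of about forty subjects:
142/19/84 features (structural, SUVR, diffusion), 10/3/8 informative,
effect sizes 1.2/1.5/1.0 (amyloid > atrophy > diffusion, the ordering
typical of AD ROI studies), block size 5, block correlation 0.3 (a free
parameter: real inter-feature correlation structure is not characterized
by desk data), latent loading 0. The external cohort reuses the internal
mechanism on an independent seed stream and maps every value to
`shift + scale·x` (defaults 0.5 and 1.2 — a modest scanner/site shift);
the scale is applied before the shift. A `subject_dropout` fraction can
drop random subjects per modality to emulate partial multimodal overlap.

What the generator does *not* emulate: heavy-tailed or skewed feature
distributions, site/batch structure within a cohort, covariate effects
(age, sex), longitudinal correlation, label noise, and realistic
atlas-driven correlation topology. Passing tests therefore demonstrate
correctness and calibration of the *machinery* under a known generating
model, not clinical performance.

## Feature selection

**EBM.** Each of `n_runs = 2000` iterations draws a class-stratified
80/20 subject split (the fraction mirrors the classifier's evaluation
environment), a uniform random subset of `subset_size = 8` features, and
fits a bootstrap CART forest on the training portion restricted to the
subset; mean impurity importance over a feature's appearances is its
score. Features scoring below `0.55 ×` the best are removed; removal is
strictly "lesser than", so a boundary feature survives. The forest is a
compact jitted implementation (Gini impurity, per-node √p feature
subsampling, trees grown to purity, per-tree-normalized
mean-decrease-in-impurity), kept deliberately small and fast because the
procedure fits tens of thousands of forests on ~32-subject tables; its
importances are cross-checked against scikit-learn's
`RandomForestClassifier` in the test suite. Default 500 trees per
iteration.

A caveat worth knowing: impurity importance concentrates on the locally
best feature, so when several informative features share every subset
(small p), the runner-up features can fall below the 0.55 filter. With
many features and small subsets each informative feature usually appears
without its peers and scores are comparable — the regime the method is
designed for.

**FBM.** Classical equal-variance Student t-test per feature (Welch
available behind a switch), two-sided; features with p > 0.05 are
removed and survivors ranked by |t| (the sign carries no selection
meaning).

**Correlation pruning.** Pearson r is computed over all subjects pooled,
on raw pre-standardization values. Stage 1 removes |r| > 0.55 against
the top-ranked feature; stage 2 walks survivors in rank order from the
second onward, each anchor removing lower-ranked survivors with
|r| > 0.70. Both thresholds are strict inequalities. The surviving
ranking is truncated to 8 features; fewer survivors are returned as-is.
A constant feature makes r undefined and is a named error. All ranking
ties break lexicographically on the feature name, for determinism.

## Classification

Standardization uses training-subject mean and sample standard deviation
(n−1 denominator); test and external subjects are always transformed
with training parameters — never refit — so injected distribution shifts
survive the transform (asserted in tests). The SVM uses the RBF kernel
with C = 0.1 and γ defined explicitly as 1/(n_features × mean
per-feature variance of the training matrix); after standardization this
is numerically the familiar "scale" heuristic. Probabilities come from a
Platt-style logistic sigmoid fitted on training decision values
(L2-regularized with C = 1, keeping the fit finite on separable data);
any monotone map to [0, 1] serves the fusion contract, and the fitted
coefficients are recorded in model metadata. The decision threshold is
0.5 with ties labeled AD.

Evaluation repeats a class-stratified 80/20 split 2,000 times (per-class
test counts rounded to nearest, minimum one per class), refitting
standardization, SVM and calibration each cycle. Per-cycle accuracy,
sensitivity, specificity, balanced accuracy (mean of the previous two),
ROC and trapezoidal AUC are stored; the trapezoidal AUC is identical to
the Mann-Whitney rank statistic U/(n₁n₀), asserted to 1e-12. The mean
ROC uses vertical averaging: each cycle's step curve is right-continuous
step-interpolated onto a fixed FPR grid (101 points, 0.00–1.00) with
(0,0) and (1,1) anchored, and TPRs are averaged pointwise. The grid and
the averaging convention are implementation choices; the mean AUC equals
the arithmetic mean of per-cycle AUCs exactly and is not the area under
the mean curve.

## Late fusion

`Y_i = Σ_k c_k y_ki` with convex weights; equal weights are the default
scheme and the only one reported (arbitrary weight grids are supported
but off by default). Base models are trained once on the full
selection/training cohort and applied to a disjoint ensemble cohort;
subjects are inner-joined by identifier across the involved modalities,
so partial overlap shrinks the evaluation set rather than crashing.
Ensemble ROC/AUC is computed from the fused probabilities (not by
averaging ROC curves). One-hot weights reproduce the base classifier
bit-exactly; convexity, permutation equivariance and linearity in the
weights are asserted on random instances.

## Orchestration and determinism

`run_experiment` derives every stage seed from one master seed, logs
derived seeds and per-stage wall time, and writes metrics JSON/CSV, ROC
CSVs, selection audit JSONs and a manifest (config + seeds + version).
Artifacts contain no timestamps; two runs with the same config and seed
are byte-identical. A single-modality configuration skips the ensemble
stage with a logged notice.

## Problem sizes used in the shipped checks

The default experiment (and `scripts/acceptance.py`) uses 20 subjects
per group, the full 2,000 selection iterations and 2,000 evaluation
cycles per modality. Test-suite simulations use smaller cohorts and
cycle counts chosen for statistical sufficiency of each assertion:
null-calibration runs the full 2,000 cycles; planted-feature recovery
runs 20 replicate seeds at 2,000 selection iterations; the
Monte-Carlo-versus-exhaustive selection comparison uses all C(10,8) = 45
subsets × 100 repeats against 5,000 random-subset runs; determinism is
checked at 200 cycles.

## Known limitations

* Impurity-based importances are biased toward features offering more
  split points; with continuous unit-variance features this is benign,
  but mixed-scale data should be inspected.
* The Platt calibration is fitted on the same training data as the SVM,
  so probabilities are optimistic near the margin; ranking metrics (AUC)
  are unaffected, and fusion only requires monotone comparability.
* The EBM importance filter interacts with subset size (see caveat
  above); the shipped defaults match the intended many-features regime.
* Accuracy-type metrics on 8-subject test splits are coarse (multiples
  of 1/8); their cycle means are stable but per-cycle values are not.
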