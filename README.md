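# roifuse

Multimodal classification of Alzheimer's disease (AD) versus cognitively
normal (CN) subjects from region-of-interest (ROI) imaging features, with
weighted late fusion of per-modality classifiers.

Small clinical neuroimaging cohorts typically provide a few tens of
subjects but hundreds of candidate ROI features per imaging modality —
gray-matter volumes and cortical thickness from structural MRI, regional
standard-uptake-value ratios (SUVR) from amyloid PET, fractional
anisotropy (FA) and mean diffusivity (MD) from diffusion tensor imaging.
`roifuse` implements a complete, reproducible pipeline for this setting,
together with a synthetic cohort generator that emulates its statistical
structure, so every stage can be exercised and validated without access
to clinical data.

## The method

For each modality *m* with feature matrix `X` and diagnosis `y ∈ {0 (CN),
1 (AD)}`:

1. **Feature selection.** Either the *embedded* method (EBM): over 2,000
   Monte-Carlo iterations, draw a balanced subject split and a uniform
   random subset of 8 features, fit a random forest, and record each
   subset feature's impurity importance; rank features by mean importance
   and drop those below 0.55 × the best feature. Or the *filter* method
   (FBM): a per-feature two-sample Student t-test, dropping features with
   p > 0.05 and ranking survivors by |t|. Both feed a two-stage Pearson
   pruning — remove features with |r| > 0.55 against the top-ranked
   feature, then walk the survivors in rank order removing lower-ranked
   features with |r| > 0.70 against each anchor — and a final truncation
   to at most 8 features.
2. **Classification.** Features are standardized with training-subject
   statistics, `x′ = (x − x̄)/s`, and fed to an RBF-kernel SVM (C = 0.1,
   γ = 1/(n_features × mean training-feature variance)), whose decision
   values are mapped to probabilities by a Platt sigmoid fitted on
   training data. Performance is estimated by 2,000 class-stratified
   80/20 train/test cycles, reporting mean ± sd accuracy, sensitivity,
   specificity, balanced accuracy, AUC, and the vertically averaged ROC.
3. **Late fusion.** Per-modality AD probabilities `y_ki` are combined as
   `Y_i = Σ_k c_k y_ki` with convex weights `Σ c_k = 1` (equal weights
   1/2 or 1/3 by default); every modality subset is evaluated against the
   single-modality baselines on the same subjects, on a held-out ensemble
   cohort and on a distribution-shifted external cohort.

The synthetic generator is a Gaussian linear factor model with planted
group effects (standardized effect size *d*), block-correlated nuisance
features, and an optional cross-modality latent factor that makes two
modalities' informative features redundant — the regime in which late
fusion stops improving over the best single modality.

## Worked example

```python
import roifuse as rf

cfg = rf.CohortConfig(n_per_group=20, seed=3, modalities=(
    rf.ModalitySpec("smri", 30, 5, effect_size=1.5, block_rho=0.3),
    rf.ModalitySpec("pet", 15, 3, effect_size=1.5, block_rho=0.3)))
tables = rf.generate_multimodal_cohort(cfg)

sel = rf.select_features(tables["smri"],
                         rf.SelectionConfig(method="ebm", n_runs=300, seed=1))
agg, _ = rf.repeated_holdout_evaluation(tables["smri"], sel.selected,
                                        rf.SvmConfig(),
                                        rf.EvalConfig(n_cycles=200, seed=5))
print(agg.mean)

models = {m: rf.train_modality_model(
              t, rf.select_features(t, rf.SelectionConfig(n_runs=200, seed=2)).selected)
          for m, t in tables.items()}
test = rf.generate_multimodal_cohort(
    rf.CohortConfig(n_per_group=20, seed=99, modalities=cfg.modalities))
singles, combos = rf.enumerate_combinations(models, test)
for k, v in {**singles, **combos}.items():
    print(k, round(v.auc, 3))
```

prints (exact output of this snippet):

```
{'accuracy': 0.83, 'sensitivity': 0.775, 'specificity': 0.885, 'balanced_accuracy': 0.83, 'auc': 0.8775}
pet 0.84
smri 0.92
('pet', 'smri') 0.942
```

The structural-MRI classifier alone reaches a mean holdout AUC of 0.88 on
its own cohort; on the held-out test cohort the two single-modality
models score 0.84 and 0.92, and their equal-weight fusion improves on the
better one (0.942) because the two planted signals are independent. With
`latent_loading` near 1 on both modalities the fusion gain disappears —
the redundant-modality regime.

The same pipeline is scriptable from the shell:

```
roifuse simulate --seed 3 --n-per-group 20 --out cohort/
roifuse select --table cohort/internal_smri.csv --method ebm --seed 1 --out sel.json
roifuse evaluate --table cohort/internal_smri.csv --features sel.json \
    --seed 5 --n-cycles 2000 --out-prefix smri
roifuse run-all --seed 7 --out run/
roifuse report --run-dir run/
```

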