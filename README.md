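# mcistab

Classification of mild-cognitive-impairment (MCI) subtypes from MRI-derived
morphometric feature tables, with stability feature selection, cluster-based
class rebalancing, a weighted soft-voting ensemble, and Monte Carlo
cross-validated evaluation.

## The problem

Mild cognitive impairment splits into an amnestic (aMCI, memory-predominant)
and a non-amnestic (naMCI) subtype with different likely trajectories toward
dementia. Separating aMCI from naMCI and both from cognitively normal (CN)
elderly using structural MRI is hard for two reasons typical of
population-based neuroimaging:

- **p ≫ n with unstable selection.** A few hundred subjects against 178
  morphometric measurements per timepoint (12 sulcal, 68 cortical thickness,
  68 cortical gray-matter volume, 14 subcortical volume, 16 regional
  white-matter-hyperintensity volume; 356 when baseline and 2-year follow-up
  are combined into per-feature means and changes). Feature selection on such
  data has enormous variance across resamples.
- **Class imbalance.** Community cohorts contain many more CN than MCI
  subjects (e.g. 115 CN vs 42 aMCI vs 27 naMCI), which biases classifiers
  toward the majority class.

`mcistab` is aimed at biostatisticians and neuroimaging researchers who want
this analysis as a tested, seedable library rather than a one-off script. The
original cohort it models is private, so the package ships a synthetic-cohort
generator with plantable ground truth (group mean shifts in Cohen's *d* units
and group-specific 2-year change), which every test and the acceptance script
use.

## The method

For a binary task (aMCI vs CN, naMCI vs CN, naMCI vs aMCI) and one feature
set (baseline, wave-2 or longitudinal), each Monte Carlo iteration runs:

1. **Stratified 9:1 split** (10 independent iterations; stratified shuffle
   split). Test rows are never resampled and never touch selection.
2. **0–1 scaling** x ↦ (x − min)/(max − min), fitted on training rows only.
3. **Hybrid rebalancing** (×3, giving three resampled training sets):
   the minority class of current size Ns is clustered with K-means into
   k = max(1, ⌊Ns/3⌋) clusters and the k centroids appended, repeating until
   Ns ≥ ⅔·M (M = original majority size); the majority is then reduced with
   K-medoids — whose centres are actual subjects — to match the minority.
4. **Stability selection** on each resampled set: 100 stratified random
   half-splits; on half A an ANOVA-F filter keeps the top 100 features; on
   half B SVM recursive feature elimination (linear kernel, smallest squared
   weight dropped per round) keeps 20 of those; each survivor's tally is
   incremented (per-run frequency ∈ [0, 100], total mass 100 × 20 = 2,000).
   The final size N_f ∈ {10, 9, 8} is chosen by mean recall
   Tp/(Tp + Fn) of the affected class over 5 stratified 50/50
   train/validation splits with an RBF-kernel SVM; selected features are also
   described by two-sided Welch t-tests.
5. **Weighted soft voting**: SVM (RBF, Platt-calibrated), logistic
   regression and random forest at default hyperparameters, probabilities
   combined as p = Σ w·p_c / Σ w with w = (1, 4, 1).
6. **Majority vote** of the three per-resample models labels each test
   subject; the mean positive-class probability is the AUC score.

Accuracy, sensitivity, specificity and AUC are averaged over the 10
iterations, and selection frequencies are summed over 3 resamples × 10
iterations, so each feature's aggregated frequency is capped at
3 × 100 × 10 = 3,000 — the ranked top-10 of this tally is the biomarker
report.

## Worked example

```python
from mcistab import make_fixture, run_experiment, ExperimentConfig, SelectionConfig

fx = make_fixture("separable")   # 30 aMCI + 30 CN, 150 features, 5 planted at d=2.5
cfg = ExperimentConfig(
    task="aMCI_vs_CN",
    feature_set="baseline",
    selection=SelectionConfig(n_subsamples=25, rfe_step=5),  # reduced for speed
    seed=11,
)
report = run_experiment(cfg, fx.baseline, fx.wave2)
print(report.metrics_frame().round(3).to_string(index=False))
print(report.top_features.head(6).to_string(index=False))
print("planted:", fx.truth.planted_names("aMCI"))
```

prints

```
      task feature_set  accuracy  sensitivity  specificity  auc
aMCI_vs_CN    baseline       1.0          1.0          1.0  1.0
        feature  frequency            p
   sulcal__f003        750 3.313942e-15
thickness__f029        750 1.728614e-15
gm_volume__f008        750 1.032927e-15
gm_volume__f043        750 1.673067e-14
      wmh__f010        750 4.282007e-15
gm_volume__f016        361 2.991182e-03
planted: ('sulcal__f003', 'thickness__f029', 'gm_volume__f008', 'gm_volume__f043', 'wmh__f010')
```

All five planted biomarkers saturate the aggregated frequency cap
(3 × 25 × 10 = 750 here) and separate cleanly from the noise features, and
the held-out metrics are perfect on this strongly separable cohort.

The same pipeline is available from the shell:

```bash
mcistab simulate --config cohort.yaml --out-dir data/
mcistab run --baseline data/baseline.csv --wave2 data/wave2.csv \
        --task naMCI_vs_aMCI --feature-set longitudinal --out-dir results/
mcistab select --in train.csv --out selection.json       # selection only
mcistab rebalance --in train.csv --out rebalanced.csv --task naMCI_vs_CN
```

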