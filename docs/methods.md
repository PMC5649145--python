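# Methods

This note documents the statistical model behind `mcistab`, the choices made
where the protocol was genuinely open, the synthetic-cohort generator's
assumptions, and the numerical details a maintainer would need.

## Pipeline contract

The unit of analysis is a `FeatureTable`: subjects × named morphometric
features with a timepoint tag and a per-subject diagnosis (CN / aMCI /
naMCI). The canonical cross-sectional layout has 178 features in five
families (12 sulcal, 68 cortical thickness, 68 cortical GM volume, 14
subcortical volume, 16 WMH volume); names are family-prefixed
(`thickness__…`) so the layout is validated from column names alone. The
longitudinal set doubles this to 356: for each feature, the arithmetic mean
of the two timepoints and the change, defined as **follow-up minus
baseline** so that atrophy produces negative thickness/volume changes.
Longitudinal labels are taken from the follow-up wave, which carries the
diagnostic ground truth. Subjects must be present at both timepoints;
missing values are rejected rather than imputed (the emulated acquisition
protocol excluded failed-QC scans instead of imputing).

Every fold of the evaluation honours a strict leakage contract: the 0–1
scaler, the rebalancer, stability selection and all classifiers see training
rows only. This is enforced structurally — `run_fold` never reads test
labels — and by a test that permutes test labels and asserts bit-identical
training artifacts and predictions.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `cv_iterations` / `test_fraction` | 10 / 0.1 | stratified Monte Carlo 9:1 splits |
| `n_resamples` | 3 | rebalanced training sets per fold (odd, so the majority vote cannot tie) |
| oversampling stop | ⅔ × original majority | minority grows by k = max(1, ⌊Ns/3⌋) centroids per K-means round; overshoot kept |
| `undersample` | `balanced` | majority K-medoids target = final minority size (also `none`, `ratio_3_2`) |
| `n_subsamples` | 100 | stability half-splits per selection run |
| `filter_keep` / `wrapper_keep` | 100 / 20 | ANOVA-F filter width; SVM-RFE survivor count |
| `nf_grid` / `nf_repeats` | (10, 9, 8) / 5 | candidate final set sizes; recall-validation splits |
| `rfe_step` | 1 | features dropped per RFE round (raise for speed) |
| `weights` | (1, 4, 1) | SVM : logistic : random-forest soft-vote weights |
| `svm_c` | 1.0 | regularisation of the internal SVMs (library default) |

All component classifiers run at library defaults, matching the reference
protocol; the voting weights are exposed because the 1:4:1 setting was an
experimental choice favouring sensitivity, not a derived constant.

## Design choices where the protocol was open

- **RFE estimator.** Recursive elimination needs per-feature weights, so the
  wrapper uses a linear-kernel SVM and drops the smallest-|w|² feature per
  round; the RBF kernel applies only to the N_f-validation classifier, where
  it is part of the protocol.
- **Positive class.** Sensitivity/recall/AUC are oriented toward the
  clinically affected (and minority) group: aMCI in aMCI-vs-CN, naMCI in the
  other two tasks.
- **Stratification.** Half-splits and the 50/50 N_f-validation splits are
  stratified by class; unstratified halves of a 27-subject minority could
  lose a class entirely. The same five validation splits are shared across
  the N_f grid so candidates are compared on identical data.
- **Tie-breaks.** Equal mean recall → the smaller N_f (parsimony); equal
  selection frequency → the larger full-training ANOVA F.
- **Scaling before resampling.** The 0–1 scaler is fitted on the full
  training fold before rebalancing, and clustering runs in that scaled
  space: Euclidean distances on raw mm³-volumes vs mm-thicknesses would be
  dominated by the volume families.
- **Undersampling target.** The oversampling stop (⅔ of the majority) is
  stated by the protocol, the undersampling target is not. The default
  undersamples the majority to the final minority size, producing a balanced
  set and making the medoid step meaningful; a 3:2 target would be a near
  no-op since the minority already reached ⅔·M. Both alternatives remain
  available via `undersample=`.
- **t-test variant.** Welch (unequal variances), two-sided — the safer
  default when group spreads differ.
- **AUC score under majority voting.** Vote labels alone define no ranking;
  the unweighted mean of the three models' combined positive-class
  probabilities is used as the score.
- **Probability calibration.** The RBF SVM emits probabilities through
  sigmoid (Platt) calibration fitted on the training data
  (`CalibratedClassifierCV(SVC(), ensemble=False)`), since soft voting needs
  probabilities from all three components.

## Synthetic cohorts

`generate_cohort` emulates a two-timepoint, three-group elderly cohort at
the follow-up group sizes 115 CN / 42 aMCI / 27 naMCI. Per subject i,
feature j, group g:

    baseline latent   z_ij  = δ_{g,j} + u_ij
    follow-up latent  z'_ij = δ_{g,j} + s_{g,j} + ρ·u_ij + √(1−ρ²)·u'_ij

with δ the planted cross-sectional shift (Cohen's d units), s the planted
2-year slope (SD units), ρ = 0.8 the within-subject test–retest correlation,
and u, u' unit-variance noise with within-family equicorrelation 0.3 by
default — a stand-in for the unknown covariance of real morphometrics;
correlated nuisance features are what stress a selection procedure. Latents
map through affine per-family transforms (thickness ≈ 2.5 ± 0.25 mm, GM
volumes ≈ 5200 ± 900 mm³, …) so the observed table carries genuinely mixed
units and 0–1 scaling is non-trivial; affine maps also preserve planted
effect sizes exactly, which the generator-calibration tests rely on.

Three documented fixtures: `separable` (30 + 30 subjects, 150 features, 5
features planted at d = 2.5 with mild decline), `null` (40 + 40, 100
features, nothing planted, no family correlation) and `imbalanced` (the
study-sized 115/42/27 cohort with moderate planted effects per patient
group).

**What passing tests do not show.** The generator draws independent Gaussian
families with equicorrelated noise; real cortical anatomy has spatially
structured covariance, scanner/site effects, non-Gaussian WMH distributions
and missing data, none of which are modelled. Recovery results on `separable`
(d = 2.5) demonstrate correctness of the machinery, not expected performance
on clinical data, where effects are an order of magnitude weaker.

## Numerical details

- ANOVA F is computed from between/within sums of squares; a constant
  feature yields 0/0 and is assigned F = 0 (degenerate columns must not
  crash the filter); a feature constant within groups but differing between
  them yields F = ∞ and ranks first. For two groups F equals the squared
  pooled-variance t statistic (tested to 1e-10 relative).
- K-means uses k-means++ seeding with 10 restarts per call; K-medoids is a
  seeded alternate-style implementation (random distinct initial medoids,
  then each medoid moves to the in-cluster point minimising summed Euclidean
  distance, to convergence or 300 rounds; ties break to the lowest row
  index). Its outputs are exact input rows by construction and it matches
  brute-force enumeration on tiny instances.
- Min–max scaling maps constant training columns to 0; test values reuse
  training bounds and are not clipped.
- Welch p-values with zero variance in both groups are undefined and
  reported as 1.0 with a `degenerate` flag.
- Single-class test folds (possible at n_test ≈ 7 for naMCI) yield NaN for
  the undefined metrics, which are excluded from experiment means.
- Seeding: one master seed per experiment is expanded through
  `numpy.random.SeedSequence` spawning into independent children per
  (fold, resample, subsample, model), so fold membership is invariant to
  `n_resamples`, and every run is bit-reproducible.

## Problem sizes used by the test suite and acceptance script

The structural-constant checks run the full 100-subsample protocol on
narrow (30-feature) tables, where it completes in seconds. The end-to-end
recovery and null-calibration suites run the pipeline at 25 subsamples and
RFE step 5 on the 60–80-subject fixtures — sizes chosen so the whole loop
(10 folds × 3 resamples) retains its statistical structure while a 10-seed
replication stays fast; the planted d = 2.5 signal makes recovery
insensitive to this reduction. The acceptance script additionally runs one
complete default-protocol experiment (10 × 3 × 100, step-1 RFE) on the
separable cohort.

## Known limitations

- Binary tasks only; the three-group problem is handled as three pairwise
  comparisons, as in the reference protocol.
- No hyperparameter search; all component classifiers run at library
  defaults.
- The K-medoids heuristic is a local optimiser; with k close to n this is
  immaterial (most clusters are singletons), but it is not exact PAM.
- Selection frequencies aggregated across folds are correlated (folds share
  ~80% of their training rows), so the 0–3,000 scale is a ranking device,
  not an independent replication count.
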