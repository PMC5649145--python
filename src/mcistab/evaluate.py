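"""Monte Carlo cross-validated evaluation of the full pipeline.

One experiment runs a binary diagnostic task (aMCI vs CN, naMCI vs CN, or
naMCI vs aMCI) on one feature set (baseline, wave-2, or longitudinal) through
a stratified shuffle-split Monte Carlo cross-validation: 10 independent
stratified 9:1 train/test splits. Within each fold, a 0-1 scaler is fitted on
the training rows; the training set is rebalanced three times; per resample,
stability selection picks an optimal feature set and a weighted soft-voting
model is fitted on it; the three models classify the untouched test rows by
majority vote. Accuracy, sensitivity, specificity and AUC are averaged over
folds, and per-feature selection frequencies are summed over the
3 resamples x 10 folds (so each feature's aggregated frequency is capped at
3 x 100 x 10 = 3,000), yielding the ranked-biomarker report.

The test rows of a fold are never resampled and never seen by the scaler,
the rebalancer, the selector or the models; test labels enter only the
metric computation.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedShuffleSplit

from ._seeding import child_seeds
from .ensemble import DEFAULT_WEIGHTS, ModelTriplet, apply_scaler, fit_scaler, fit_voting
from .feature_schema import FeatureTable, build_longitudinal
from .rebalance import rebalance
from .stability import (
    SelectionConfig,
    SelectionResult,
    choose_optimal_set,
    run_subsampling,
    ttest_selected,
)

#: Binary tasks as (positive, negative) class — the positive class is the
#: clinically affected / minority group of the comparison.
TASKS: dict[str, tuple[str, str]] = {
    "aMCI_vs_CN": ("aMCI", "CN"),
    "naMCI_vs_CN": ("naMCI", "CN"),
    "naMCI_vs_aMCI": ("naMCI", "aMCI"),
}

FEATURE_SETS = ("baseline", "wave2", "longitudinal")


@dataclass(frozen=True)
class ExperimentConfig:
    task: str = "aMCI_vs_CN"
    feature_set: str = "baseline"
    cv_iterations: int = 10
    test_fraction: float = 0.1
    n_resamples: int = 3
    undersample: str = "balanced"
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}; one of {sorted(TASKS)}")
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(f"feature_set must be one of {FEATURE_SETS}")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.cv_iterations < 1:
            raise ValueError("cv_iterations must be >= 1")
        if self.n_resamples < 1 or self.n_resamples % 2 == 0:
            raise ValueError("n_resamples must be odd (majority vote)")
        self.selection.validate()

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "selection" in d and isinstance(d["selection"], dict):
            sel = dict(d["selection"])
            if "nf_grid" in sel:
                sel["nf_grid"] = tuple(sel["nf_grid"])
            d["selection"] = SelectionConfig(**sel)
        if "weights" in d:
            d["weights"] = tuple(d["weights"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["weights"] = list(self.weights)
        d["selection"]["nf_grid"] = list(self.selection.nf_grid)
        return d


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts; the positive class is the affected group."""

    tp: int
    fn: int
    tn: int
    fp: int

    @classmethod
    def from_predictions(
        cls, y_true: np.ndarray, y_pred: np.ndarray, pos_label: str
    ) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        pos = y_true == pos_label
        return cls(
            tp=int(np.sum(pos & (y_pred == pos_label))),
            fn=int(np.sum(pos & (y_pred != pos_label))),
            tn=int(np.sum(~pos & (y_pred != pos_label))),
            fp=int(np.sum(~pos & (y_pred == pos_label))),
        )


@dataclass(frozen=True)
class Metrics:
    """Fold metrics; an undefined entry (single-class fold) is NaN."""

    accuracy: float
    sensitivity: float
    specificity: float
    auc: float


def compute_metrics(
    counts: ConfusionCounts,
    y_true: np.ndarray,
    scores: np.ndarray,
    pos_label: str,
) -> Metrics:
    """Accuracy, sensitivity, specificity, and rank-based AUC.

    sensitivity = Tp/(Tp+Fn); specificity = Tn/(Tn+Fp); AUC is the
    probability that a random positive's score exceeds a random negative's
    (ties counted 1/2). Metrics whose denominator class is absent from the
    test fold are NaN and excluded from experiment means.
    """
    n = counts.tp + counts.fn + counts.tn + counts.fp
    if n == 0:
        raise ValueError("empty test fold")
    accuracy = (counts.tp + counts.tn) / n
    n_pos = counts.tp + counts.fn
    n_neg = counts.tn + counts.fp
    sensitivity = counts.tp / n_pos if n_pos else math.nan
    specificity = counts.tn / n_neg if n_neg else math.nan
    if n_pos and n_neg:
        auc = float(roc_auc_score(np.asarray(y_true) == pos_label, scores))
    else:
        auc = math.nan
    return Metrics(accuracy, sensitivity, specificity, auc)


def shuffle_split(
    labels: np.ndarray,
    n_splits: int = 10,
    test_fraction: float = 0.1,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified Monte Carlo splits: independent random 9:1 partitions.

    Per split the class proportions are preserved to within rounding; train
    and test are disjoint and cover all indices.
    """
    labels = np.asarray(labels)
    sss = StratifiedShuffleSplit(
        n_splits=n_splits, test_size=test_fraction, random_state=seed
    )
    return [
        (np.sort(tr), np.sort(te)) for tr, te in sss.split(np.zeros(len(labels)), labels)
    ]


@dataclass
class FoldResult:
    predictions: np.ndarray
    probabilities: np.ndarray  # mean positive-class probability (AUC score)
    selections: list[SelectionResult]
    triplet: ModelTriplet


def run_fold(
    values: np.ndarray,
    labels: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    config: ExperimentConfig,
    seed: int,
) -> FoldResult:
    """Run one cross-validation fold end to end.

    Only ``labels[train_idx]`` is ever read: scaling, rebalancing, selection
    and model fitting all happen strictly inside the training rows, and the
    test rows are classified untouched.
    """
    pos_label, _ = TASKS[config.task]
    x_tr = values[train_idx]
    y_tr = np.asarray(labels)[train_idx]
    scaler = fit_scaler(x_tr)
    x_tr_s = apply_scaler(scaler, x_tr)
    x_te_s = apply_scaler(scaler, values[test_idx])

    selections: list[SelectionResult] = []
    models = []
    for r_seed in child_seeds(seed, config.n_resamples):
        s_rebal, s_subsample, s_choose, s_fit = child_seeds(r_seed, 4)
        rb = rebalance(x_tr_s, y_tr, seed=s_rebal, undersample=config.undersample)
        freq = run_subsampling(rb.values, rb.labels, config.selection, seed=s_subsample)
        sel = choose_optimal_set(
            rb.values, rb.labels, freq, config.selection, seed=s_choose, pos_label=pos_label
        )
        selections.append(sel)
        models.append(
            fit_voting(rb.values, rb.labels, sel.feature_indices, seed=s_fit, weights=config.weights)
        )
    triplet = ModelTriplet(models=models)
    pred, prob = triplet.majority_predict(x_te_s, pos_label=pos_label)
    return FoldResult(predictions=pred, probabilities=prob, selections=selections, triplet=triplet)


@dataclass
class EvaluationReport:
    """Per-fold and averaged metrics plus the aggregated biomarker ranking."""

    config: ExperimentConfig
    per_iteration: pd.DataFrame  # one row per fold: accuracy/sensitivity/specificity/auc
    means: Metrics
    frequencies: pd.Series  # aggregated per-feature selection frequency
    top_features: pd.DataFrame  # columns: feature, frequency, p
    max_frequency: int  # theoretical cap: n_resamples * n_subsamples * cv_iterations
    chosen_nf: pd.DataFrame = None  # fold x resample chosen feature-set sizes

    def metrics_frame(self) -> pd.DataFrame:
        """Single-row summary in the shape of the headline results table."""
        return pd.DataFrame(
            [
                {
                    "task": self.config.task,
                    "feature_set": self.config.feature_set,
                    "accuracy": self.means.accuracy,
                    "sensitivity": self.means.sensitivity,
                    "specificity": self.means.specificity,
                    "auc": self.means.auc,
                }
            ]
        )


def _task_table(
    config: ExperimentConfig,
    baseline: FeatureTable,
    wave2: FeatureTable | None,
) -> FeatureTable:
    if config.feature_set == "baseline":
        table = baseline
    elif config.feature_set == "wave2":
        if wave2 is None:
            raise ValueError("wave2 table required for feature_set='wave2'")
        table = wave2
    else:
        if wave2 is None:
            raise ValueError("wave2 table required for feature_set='longitudinal'")
        table = build_longitudinal(baseline, wave2)
    return table.restrict_labels(TASKS[config.task])


def run_experiment(
    config: ExperimentConfig,
    baseline: FeatureTable,
    wave2: FeatureTable | None = None,
) -> EvaluationReport:
    """Run the full Monte Carlo cross-validated experiment.

    Seeding: the master seed spawns one child for fold membership and one per
    fold, so fold membership is invariant to ``n_resamples``.
    """
    config.validate()
    table = _task_table(config, baseline, wave2)
    values, labels = table.values, table.label_array()
    pos_label, _ = TASKS[config.task]

    split_seed, *fold_seeds = child_seeds(config.seed, 1 + config.cv_iterations)
    folds = shuffle_split(labels, config.cv_iterations, config.test_fraction, split_seed)

    rows = []
    nf_rows = []
    agg_freq = np.zeros(table.n_features, dtype=int)
    for i, ((train_idx, test_idx), f_seed) in enumerate(zip(folds, fold_seeds)):
        result = run_fold(values, labels, train_idx, test_idx, config, f_seed)
        y_te = labels[test_idx]
        counts = ConfusionCounts.from_predictions(y_te, result.predictions, pos_label)
        m = compute_metrics(counts, y_te, result.probabilities, pos_label)
        rows.append({"iteration": i, **asdict(m)})
        nf_rows.append([sel.chosen_nf for sel in result.selections])
        for sel in result.selections:
            agg_freq += sel.frequencies

    per_iteration = pd.DataFrame(rows).set_index("iteration")
    means = Metrics(
        *(float(np.nanmean(per_iteration[c])) for c in
          ("accuracy", "sensitivity", "specificity", "auc"))
    )
    frequencies = pd.Series(agg_freq, index=list(table.feature_names), name="frequency")

    top = frequencies.sort_values(ascending=False, kind="stable").head(10)
    top_idx = [table.feature_names.index(f) for f in top.index]
    p_values, _ = ttest_selected(values, labels, top_idx)
    top_features = pd.DataFrame(
        {"feature": top.index, "frequency": top.to_numpy(), "p": p_values}
    ).reset_index(drop=True)

    cap = config.n_resamples * config.selection.n_subsamples * config.cv_iterations
    return EvaluationReport(
        config=config,
        per_iteration=per_iteration,
        means=means,
        frequencies=frequencies,
        top_features=top_features,
        max_frequency=cap,
        chosen_nf=pd.DataFrame(
            nf_rows, columns=[f"resample_{r}" for r in range(config.n_resamples)]
        ),
    )


def compare_runs(
    report_a: EvaluationReport, report_b: EvaluationReport, metric: str = "accuracy"
) -> tuple[float, float]:
    """Two-sided Welch t-test between two runs' per-iteration metric values.

    Used to ask whether two method configurations (e.g. baseline vs
    longitudinal features) differ significantly at p < 0.05 across the Monte
    Carlo iterations. Returns (t statistic, p-value).
    """
    a = report_a.per_iteration[metric].dropna()
    b = report_b.per_iteration[metric].dropna()
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)
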