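"""Stability feature selection by subsample frequency.

Filter and wrapper selection are embedded in a subsampling loop to tame the
huge variance of selection on small-n / large-p neuroimaging data: the
training set is randomly half-split 100 times; on one half a univariate
ANOVA-F filter keeps the top 100 features, on the other half SVM-based
recursive feature elimination (linear kernel, squared-weight criterion)
reduces those candidates to 20. Each surviving feature increments a tally, so
per run a feature's selection frequency lies in [0, 100] and the tallies sum
to 100 x 20 = 2,000.

The final set size Nf is chosen from a small grid (10, 9, 8) by validated
recall: for each Nf, five stratified 50/50 splits train an RBF-kernel SVM on
the top-Nf features and score recall of the positive (clinically affected)
class on the held-out half; the Nf with the best mean recall wins (ties go to
the smaller, more parsimonious set). Selected features are additionally
described by two-sided Welch t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.feature_selection import RFE
from sklearn.metrics import recall_score
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

from ._seeding import child_seeds


@dataclass(frozen=True)
class SelectionConfig:
    """Knobs of the selection procedure; defaults are the reference protocol.

    ``rfe_step`` is the number of features eliminated per RFE round (1 is the
    fully recursive variant; larger steps trade fidelity for speed).
    ``svm_c`` is the regularisation constant shared by the internal linear and
    RBF classifiers (library default 1.0).
    """

    n_subsamples: int = 100
    filter_keep: int = 100
    wrapper_keep: int = 20
    nf_grid: tuple[int, ...] = (10, 9, 8)
    nf_repeats: int = 5
    rfe_step: int = 1
    svm_c: float = 1.0

    def validate(self, n_features: int | None = None) -> None:
        if self.wrapper_keep > self.filter_keep:
            raise ValueError("wrapper_keep must be <= filter_keep")
        if max(self.nf_grid) > self.wrapper_keep:
            raise ValueError("max(nf_grid) must be <= wrapper_keep")
        if self.n_subsamples < 1 or self.nf_repeats < 1 or self.rfe_step < 1:
            raise ValueError("n_subsamples, nf_repeats and rfe_step must be >= 1")


@dataclass
class SelectionResult:
    """Outcome of one full selection run on one training set."""

    chosen_nf: int
    feature_indices: np.ndarray  # ordered by descending frequency (F-value tie-break)
    frequencies: np.ndarray  # per-feature tally over the subsampling loop
    mean_recalls: dict[int, float]  # per candidate Nf
    p_values: np.ndarray | None = None  # Welch t-test per selected feature
    degenerate: np.ndarray | None = None  # flags: p undefined (zero variance)

    @property
    def n_selected(self) -> int:
        return len(self.feature_indices)


def anova_f(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """One-way ANOVA F statistic per feature (two or more groups).

    Computed directly from between/within sums of squares. Features with zero
    total variance get F = 0 (degenerate columns must not crash the filter);
    features constant within groups but differing between them get F = inf,
    which ranks them first.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    if counts.min() < 2:
        raise ValueError("every group needs >= 2 samples")
    n = values.shape[0]
    grand = values.mean(axis=0)
    ssb = np.zeros(values.shape[1])
    ssw = np.zeros(values.shape[1])
    for c, nc in zip(classes, counts):
        grp = values[labels == c]
        gm = grp.mean(axis=0)
        ssb += nc * (gm - grand) ** 2
        ssw += ((grp - gm) ** 2).sum(axis=0)
    df_b = classes.size - 1
    df_w = n - classes.size
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df_b) / (ssw / df_w)
    f[np.isnan(f)] = 0.0  # 0/0: constant feature
    return f


def anova_f_rank(values: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """F statistics and the feature order by descending F (stable on ties)."""
    f = anova_f(values, labels)
    order = np.argsort(-f, kind="stable")
    return f, order


def rfe_reduce(
    values: np.ndarray,
    labels: np.ndarray,
    keep: int,
    step: int = 1,
    c: float = 1.0,
) -> np.ndarray:
    """SVM recursive feature elimination down to ``keep`` features.

    Repeatedly fits a linear maximum-margin classifier and drops the
    feature(s) with the smallest squared weight until ``keep`` remain.
    Returns the retained column indices (ascending).
    """
    p = values.shape[1]
    if keep > p:
        raise ValueError(f"cannot keep {keep} of {p} features")
    if keep == p:
        return np.arange(p)
    rfe = RFE(
        SVC(kernel="linear", C=c), n_features_to_select=keep, step=step
    ).fit(values, labels)
    return np.flatnonzero(rfe.support_)


def _check_splittable(labels: np.ndarray) -> None:
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < 4:
        raise ValueError(
            "each class needs >= 4 samples so both stratified halves keep >= 2"
        )


def run_subsampling(
    values: np.ndarray,
    labels: np.ndarray,
    config: SelectionConfig | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Tally selection frequencies over the stratified half-split loop.

    Each of the ``n_subsamples`` iterations draws a stratified random
    half-split (A, B); the ANOVA-F filter on A keeps the top ``filter_keep``
    features, RFE on B (restricted to those candidates) keeps
    ``wrapper_keep``, and the survivors' tallies are incremented.

    Returns the per-feature tally, an integer array of length ``n_features``
    with entries in [0, n_subsamples].
    """
    config = config or SelectionConfig()
    config.validate()
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    _check_splittable(labels)
    n, p = values.shape
    counts = np.zeros(p, dtype=int)
    for s in child_seeds(seed, config.n_subsamples):
        idx_a, idx_b = train_test_split(
            np.arange(n), test_size=0.5, stratify=labels, random_state=s
        )
        _, order = anova_f_rank(values[idx_a], labels[idx_a])
        candidates = order[: min(config.filter_keep, p)]
        kept = rfe_reduce(
            values[np.ix_(idx_b, candidates)],
            labels[idx_b],
            keep=min(config.wrapper_keep, len(candidates)),
            step=config.rfe_step,
            c=config.svm_c,
        )
        counts[candidates[kept]] += 1
    return counts


def _choose_nf(mean_recalls: Mapping[int, float]) -> int:
    """Best-mean-recall Nf; exact ties resolved towards the smaller set."""
    best = max(mean_recalls.values())
    return min(nf for nf, r in mean_recalls.items() if r == best)


def rank_features(
    frequencies: np.ndarray, tiebreak_f: np.ndarray
) -> np.ndarray:
    """Feature order by descending frequency, ties by descending ANOVA F."""
    return np.lexsort((-tiebreak_f, -frequencies))


def choose_optimal_set(
    values: np.ndarray,
    labels: np.ndarray,
    frequencies: np.ndarray,
    config: SelectionConfig | None = None,
    seed: int = 0,
    pos_label: str | None = None,
) -> SelectionResult:
    """Pick the final feature set from the frequency table.

    For each Nf on the grid, ``nf_repeats`` stratified 50/50 splits (shared
    across the grid, so every Nf sees the same splits) train an RBF-kernel SVM
    on the top-Nf features and compute held-out recall of ``pos_label``.
    The winning Nf's top features, ordered by frequency (ANOVA-F tie-break on
    the full training set), form the optimal set, which is then described by
    per-feature Welch t-tests.
    """
    config = config or SelectionConfig()
    config.validate()
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    frequencies = np.asarray(frequencies)
    if frequencies.size == 0 or frequencies.size != values.shape[1]:
        raise ValueError("frequency table does not match the feature matrix")
    _check_splittable(labels)
    if pos_label is None:
        # default: the minority (clinically affected) class
        classes, counts = np.unique(labels, return_counts=True)
        pos_label = classes[np.argmin(counts)]

    f_full = anova_f(values, labels)
    order = rank_features(frequencies, f_full)

    n = values.shape[0]
    splits = [
        train_test_split(
            np.arange(n), test_size=0.5, stratify=labels, random_state=s
        )
        for s in child_seeds(seed, config.nf_repeats)
    ]
    mean_recalls: dict[int, float] = {}
    for nf in config.nf_grid:
        feats = order[:nf]
        recalls = []
        for idx_tr, idx_va in splits:
            clf = SVC(kernel="rbf", C=config.svm_c).fit(
                values[np.ix_(idx_tr, feats)], labels[idx_tr]
            )
            pred = clf.predict(values[np.ix_(idx_va, feats)])
            recalls.append(
                recall_score(labels[idx_va], pred, pos_label=pos_label)
            )
        mean_recalls[nf] = float(np.mean(recalls))

    chosen = _choose_nf(mean_recalls)
    selected = order[:chosen]
    p_values, degenerate = ttest_selected(values, labels, selected)
    return SelectionResult(
        chosen_nf=chosen,
        feature_indices=selected,
        frequencies=frequencies,
        mean_recalls=mean_recalls,
        p_values=p_values,
        degenerate=degenerate,
    )


def ttest_selected(
    values: np.ndarray,
    labels: np.ndarray,
    feature_indices: Sequence[int] | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Welch t-test per selected feature.

    Returns (p_values, degenerate); where both groups have zero variance the
    p-value is undefined and reported as 1.0 with the degenerate flag set.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("t-test evaluation requires exactly 2 classes")
    a = values[labels == classes[0]]
    b = values[labels == classes[1]]
    if min(len(a), len(b)) < 2:
        raise ValueError("each class needs >= 2 samples")
    feature_indices = np.asarray(feature_indices, dtype=int)
    p = np.empty(len(feature_indices))
    degenerate = np.zeros(len(feature_indices), dtype=bool)
    for i, j in enumerate(feature_indices):
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_ind(a[:, j], b[:, j], equal_var=False)
        if np.isnan(res.pvalue):
            p[i] = 1.0
            degenerate[i] = True
        else:
            p[i] = res.pvalue
    return p, degenerate
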