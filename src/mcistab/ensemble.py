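"""Weighted soft-voting classifier and the 3-model majority vote.

One voting model combines an RBF-kernel SVM (with Platt probability
calibration), logistic regression, and a random forest, all at library-default
hyperparameters, with fixed non-negative weights (default 1:4:1 — weights the
reference protocol arrived at experimentally to favour sensitivity). Class
probabilities of the components are weight-averaged and the label is the
argmax.

Because the training set is rebalanced three times (each resample with its own
feature selection), three such models are trained per cross-validation fold
and combined by majority vote; the unweighted mean of their combined
positive-class probabilities serves as the ranking score for AUC.

Features are standardised to the 0-1 range with min/max fitted on training
data only; test values reuse the training bounds and may fall outside [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

from ._seeding import child_seeds

DEFAULT_WEIGHTS = (1.0, 4.0, 1.0)  # (SVM, LR, RF)

_BUNDLE_VERSION = 1


def fit_scaler(values: np.ndarray) -> MinMaxScaler:
    """Fit the 0-1 scaler on training data (constant columns map to 0)."""
    return MinMaxScaler().fit(np.asarray(values, dtype=float))


def apply_scaler(scaler: MinMaxScaler, values: np.ndarray) -> np.ndarray:
    """Apply training min/max; out-of-range test values are not clipped."""
    return scaler.transform(np.asarray(values, dtype=float))


def combine_probabilities(
    component_probs: Sequence[np.ndarray], weights: Sequence[float]
) -> np.ndarray:
    """Weighted average of per-component class-probability matrices.

    p = sum_c w_c p_c / sum_c w_c — rows still sum to 1, and the result is
    invariant to uniform rescaling of the weight vector.
    """
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0) or weights.sum() == 0:
        raise ValueError("weights must be non-negative and not all zero")
    stacked = np.stack([np.asarray(p, dtype=float) for p in component_probs])
    if stacked.shape[0] != len(weights):
        raise ValueError("one weight per component required")
    return np.tensordot(weights, stacked, axes=1) / weights.sum()


@dataclass
class VotingModel:
    """One fitted weighted soft-voting classifier over a feature subset."""

    svm: CalibratedClassifierCV  # Platt-calibrated RBF-kernel SVC
    lr: LogisticRegression
    rf: RandomForestClassifier
    weights: tuple[float, float, float]
    feature_indices: np.ndarray
    classes_: np.ndarray

    def _project(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(values, dtype=float)[:, self.feature_indices]

    def predict_proba(self, values: np.ndarray) -> np.ndarray:
        """Weighted-average class probabilities, columns ordered by classes_."""
        x = self._project(values)
        probs = [m.predict_proba(x) for m in (self.svm, self.lr, self.rf)]
        return combine_probabilities(probs, self.weights)

    def predict(self, values: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(values), axis=1)]

    def positive_proba(self, values: np.ndarray, pos_label: str) -> np.ndarray:
        col = int(np.flatnonzero(self.classes_ == pos_label)[0])
        return self.predict_proba(values)[:, col]


def fit_voting(
    values: np.ndarray,
    labels: np.ndarray,
    feature_indices: Sequence[int] | np.ndarray,
    seed: int = 0,
    weights: Sequence[float] = DEFAULT_WEIGHTS,
) -> VotingModel:
    """Fit the three component classifiers on identical (scaled) data.

    All components use library-default hyperparameters; the SVM is fitted with
    Platt-style probability calibration so it can take part in soft voting.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("training data has a single class")
    feature_indices = np.asarray(feature_indices, dtype=int)
    x = values[:, feature_indices]
    (s_rf,) = child_seeds(seed, 1)
    svm = CalibratedClassifierCV(SVC(kernel="rbf"), method="sigmoid", ensemble=False).fit(
        x, labels
    )
    lr = LogisticRegression().fit(x, labels)
    rf = RandomForestClassifier(random_state=s_rf).fit(x, labels)
    w = tuple(float(v) for v in weights)
    if len(w) != 3:
        raise ValueError("exactly three weights (SVM, LR, RF) required")
    return VotingModel(
        svm=svm,
        lr=lr,
        rf=rf,
        weights=w,  # type: ignore[arg-type]
        feature_indices=feature_indices,
        classes_=classes,
    )


@dataclass
class ModelTriplet:
    """An odd-sized committee of voting models (one per resampled training set).

    The default protocol uses exactly three, so a binary majority vote can
    never tie. Each member carries its own feature subset; a test instance is
    projected onto each member's subset independently.
    """

    models: list[VotingModel]

    def __post_init__(self) -> None:
        if len(self.models) < 1 or len(self.models) % 2 == 0:
            raise ValueError("committee size must be odd (default 3)")
        classes = self.models[0].classes_
        for m in self.models[1:]:
            if not np.array_equal(m.classes_, classes):
                raise ValueError("all committee members must share classes")

    @property
    def classes_(self) -> np.ndarray:
        return self.models[0].classes_

    def majority_predict(
        self, values: np.ndarray, pos_label: str | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Majority-vote labels and the mean positive-class probability.

        The probability (used as the AUC ranking score) is the unweighted mean
        of the members' combined positive-class probabilities.
        """
        if pos_label is None:
            pos_label = self.classes_[0]
        votes = np.stack([m.predict(values) for m in self.models])
        pos_votes = (votes == pos_label).sum(axis=0)
        neg_label = self.classes_[self.classes_ != pos_label][0]
        labels = np.where(pos_votes * 2 > len(self.models), pos_label, neg_label)
        probs = np.stack(
            [m.positive_proba(values, pos_label) for m in self.models]
        ).mean(axis=0)
        return labels.astype(object), probs

    def save(self, path: str | Path) -> None:
        """Serialise the committee (components, weights, features) to one file."""
        joblib.dump({"version": _BUNDLE_VERSION, "models": self.models}, path)

    @classmethod
    def load(cls, path: str | Path) -> "ModelTriplet":
        payload = joblib.load(path)
        if payload.get("version") != _BUNDLE_VERSION:
            raise ValueError(f"unsupported model bundle version: {payload.get('version')}")
        return cls(models=payload["models"])
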