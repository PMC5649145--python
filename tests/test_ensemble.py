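"""Scaling, weighted soft voting, and the 3-model majority vote."""

import numpy as np
import pytest

from mcistab import (
    ModelTriplet,
    apply_scaler,
    combine_probabilities,
    fit_scaler,
    fit_voting,
)


def training_data(separable, timepoint="baseline"):
    table = separable.task_table(timepoint)
    scaler = fit_scaler(table.values)
    return apply_scaler(scaler, table.values), table.label_array(), scaler, table


class TestScaler:
    def test_training_column_maps_to_unit_interval(self):
        s = fit_scaler(np.array([[2.0], [4.0], [6.0]]))
        np.testing.assert_allclose(
            apply_scaler(s, np.array([[2.0], [4.0], [6.0]])).ravel(), [0, 0.5, 1]
        )

    def test_test_values_not_clipped(self):
        s = fit_scaler(np.array([[2.0], [4.0], [6.0]]))
        assert apply_scaler(s, np.array([[8.0]]))[0, 0] == pytest.approx(1.5)

    def test_constant_column_maps_to_zero(self):
        s = fit_scaler(np.array([[5.0], [5.0], [5.0]]))
        np.testing.assert_allclose(apply_scaler(s, np.array([[5.0], [5.0]])), 0.0)

    def test_refit_on_scaled_data_is_identity_on_train(self, rng):
        x = rng.normal(size=(10, 4)) * 100
        xs = apply_scaler(fit_scaler(x), x)
        xss = apply_scaler(fit_scaler(xs), xs)
        np.testing.assert_allclose(xss, xs)


class TestCombineProbabilities:
    def test_weighted_average_closed_form(self):
        # class-1 component probabilities (0.9, 0.2, 0.6) at weights (1, 4, 1)
        probs = [np.array([[0.1, 0.9]]), np.array([[0.8, 0.2]]), np.array([[0.4, 0.6]])]
        out = combine_probabilities(probs, (1, 4, 1))
        assert out[0, 1] == pytest.approx((0.9 + 4 * 0.2 + 0.6) / 6)
        assert out[0, 1] == pytest.approx(0.38333, abs=1e-5)
        assert np.argmax(out[0]) == 0  # label falls to class 0

    def test_agreement_is_weight_invariant(self):
        probs = [np.array([[0.3, 0.7]])] * 3
        for w in [(1, 1, 1), (1, 4, 1), (5, 2, 9)]:
            assert combine_probabilities(probs, w)[0, 1] == pytest.approx(0.7)

    def test_rows_sum_to_one_and_scale_invariance(self, rng):
        probs = []
        for _ in range(3):
            p = rng.random((6, 2))
            probs.append(p / p.sum(axis=1, keepdims=True))
        a = combine_probabilities(probs, (1, 4, 1))
        b = combine_probabilities(probs, (10, 40, 10))
        np.testing.assert_allclose(a.sum(axis=1), 1.0)
        np.testing.assert_allclose(a, b)

    def test_bad_weights_rejected(self):
        probs = [np.ones((1, 2)) / 2] * 3
        with pytest.raises(ValueError):
            combine_probabilities(probs, (0, 0, 0))
        with pytest.raises(ValueError):
            combine_probabilities(probs, (1, -1, 1))


class TestVotingModel:
    def test_separable_training_accuracy_is_one(self, separable):
        x, y, _, _ = training_data(separable)
        planted = list(separable.truth.planted_indices("aMCI"))
        model = fit_voting(x, y, planted, seed=0)
        assert np.mean(model.predict(x) == y) == 1.0

    def test_refit_same_seed_identical_predictions(self, separable):
        x, y, _, _ = training_data(separable)
        planted = list(separable.truth.planted_indices("aMCI"))
        a = fit_voting(x, y, planted, seed=5).predict_proba(x)
        b = fit_voting(x, y, planted, seed=5).predict_proba(x)
        np.testing.assert_array_equal(a, b)

    def test_lr_only_weights_reduce_to_logistic_component(self, separable):
        x, y, _, _ = training_data(separable)
        planted = list(separable.truth.planted_indices("aMCI"))
        model = fit_voting(x, y, planted, seed=1, weights=(0, 1, 0))
        np.testing.assert_allclose(
            model.predict_proba(x), model.lr.predict_proba(x[:, planted])
        )

    def test_matches_sklearn_voting_classifier(self, separable):
        """Independent route: sklearn's soft VotingClassifier at the same weights."""
        from sklearn.calibration import CalibratedClassifierCV
        from sklearn.ensemble import RandomForestClassifier, VotingClassifier
        from sklearn.linear_model import LogisticRegression
        from sklearn.svm import SVC

        from mcistab._seeding import child_seeds

        x, y, _, _ = training_data(separable)
        planted = list(separable.truth.planted_indices("aMCI"))
        seed = 7
        ours = fit_voting(x, y, planted, seed=seed, weights=(1, 4, 1))
        (s_rf,) = child_seeds(seed, 1)
        ref = VotingClassifier(
            estimators=[
                ("svm", CalibratedClassifierCV(SVC(kernel="rbf"), method="sigmoid",
                                               ensemble=False)),
                ("lr", LogisticRegression()),
                ("rf", RandomForestClassifier(random_state=s_rf)),
            ],
            voting="soft",
            weights=[1, 4, 1],
        ).fit(x[:, planted], y)
        np.testing.assert_allclose(ours.predict_proba(x), ref.predict_proba(x[:, planted]),
                                   atol=1e-12)

    def test_probabilities_sum_to_one(self, separable):
        x, y, _, _ = training_data(separable)
        model = fit_voting(x, y, [0, 1, 2], seed=2)
        np.testing.assert_allclose(model.predict_proba(x).sum(axis=1), 1.0)

    def test_single_class_rejected(self, rng):
        x = rng.random((6, 3))
        with pytest.raises(ValueError, match="single class"):
            fit_voting(x, np.repeat("CN", 6), [0, 1], seed=0)


class _StubModel:
    """Duck-typed committee member with canned outputs."""

    def __init__(self, labels, p_pos):
        self.classes_ = np.array(["CN", "aMCI"])
        self._labels = np.asarray(labels, dtype=object)
        self._p = np.asarray(p_pos, dtype=float)

    def predict(self, values):
        return self._labels

    def positive_proba(self, values, pos_label):
        assert pos_label == "aMCI"
        return self._p


class TestModelTriplet:
    def probe(self):
        return np.zeros((1, 2))

    def test_two_to_one_majority(self):
        t = ModelTriplet([_StubModel(["aMCI"], [0.9]), _StubModel(["aMCI"], [0.8]),
                          _StubModel(["CN"], [0.1])])
        labels, probs = t.majority_predict(self.probe(), pos_label="aMCI")
        assert labels[0] == "aMCI"

    def test_unanimous_with_mean_probability(self):
        t = ModelTriplet([_StubModel(["CN"], [0.2]), _StubModel(["CN"], [0.3]),
                          _StubModel(["CN"], [0.1])])
        labels, probs = t.majority_predict(self.probe(), pos_label="aMCI")
        assert labels[0] == "CN"
        assert probs[0] == pytest.approx(0.2)

    def test_probability_is_unweighted_mean(self):
        t = ModelTriplet([_StubModel(["aMCI"], [0.6]), _StubModel(["aMCI"], [0.8]),
                          _StubModel(["CN"], [0.1])])
        _, probs = t.majority_predict(self.probe(), pos_label="aMCI")
        assert probs[0] == pytest.approx(0.5)

    def test_even_committee_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            ModelTriplet([_StubModel(["CN"], [0.5])] * 2)

    def test_three_binary_voters_never_tie(self):
        for votes in [("CN", "CN", "CN"), ("CN", "aMCI", "CN"), ("aMCI",) * 3]:
            t = ModelTriplet([_StubModel([v], [0.5]) for v in votes])
            labels, _ = t.majority_predict(self.probe(), pos_label="aMCI")
            assert labels[0] in ("CN", "aMCI")

    def test_save_load_round_trip(self, separable, tmp_path):
        x, y, _, _ = training_data(separable)
        planted = list(separable.truth.planted_indices("aMCI"))
        models = [fit_voting(x, y, planted, seed=s) for s in range(3)]
        t = ModelTriplet(models)
        path = tmp_path / "bundle.joblib"
        t.save(path)
        back = ModelTriplet.load(path)
        a_labels, a_probs = t.majority_predict(x, pos_label="aMCI")
        b_labels, b_probs = back.majority_predict(x, pos_label="aMCI")
        assert np.array_equal(a_labels, b_labels)
        np.testing.assert_array_equal(a_probs, b_probs)

    def test_heldout_accuracy_on_separable(self, separable):
        """Committee generalises: >= 0.9 held-out accuracy across 10 seeds."""
        table = separable.task_table("baseline")
        y = table.label_array()
        planted = list(separable.truth.planted_indices("aMCI"))
        from sklearn.model_selection import train_test_split

        wins = 0
        for seed in range(10):
            tr, te = train_test_split(np.arange(len(y)), test_size=0.3,
                                      stratify=y, random_state=seed)
            scaler = fit_scaler(table.values[tr])
            x_tr = apply_scaler(scaler, table.values[tr])
            x_te = apply_scaler(scaler, table.values[te])
            models = [fit_voting(x_tr, y[tr], planted, seed=s) for s in range(3)]
            labels, _ = ModelTriplet(models).majority_predict(x_te, pos_label="aMCI")
            wins += np.mean(labels == y[te]) >= 0.9
        assert wins == 10
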