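"""Ensemble training, cross-validation metrics and per-bond prediction."""

import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef

from scissile import (
    ClassifierSpec,
    Peptide,
    cross_validate,
    load_ensemble,
    predict_bond_probabilities,
    save_ensemble,
    train_ensemble,
)
from scissile.dataset import TrainingSubset
from scissile.ensemble import EnsembleModel


def separable_subset(index=0, n=40, d=4, seed=0, gap=5.0):
    """Two well-separated Gaussian blobs: any backend reaches training acc 1."""
    rng = np.random.default_rng(seed)
    X0 = rng.normal(0.0, 0.3, size=(n // 2, d))
    X1 = rng.normal(gap, 0.3, size=(n // 2, d))
    X = np.vstack([X0, X1])
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    return TrainingSubset(index=index, X=X, y=y)


class TestTrainEnsemble:
    def test_one_base_model_per_subset(self):
        subsets = [separable_subset(i, seed=i) for i in range(4)]
        model = train_ensemble(subsets, ClassifierSpec(seed=0))
        assert len(model.base_models) == 4

    def test_separable_logistic_regression_perfect_training_accuracy(self):
        s = separable_subset()
        model = train_ensemble([s], ClassifierSpec("logistic-regression", seed=0))
        pred = model.base_models[0].predict(s.X)
        assert (pred == s.y).mean() == 1.0

    def test_deterministic_given_seed(self):
        subsets = [separable_subset(i, seed=i, gap=1.0) for i in range(3)]
        X = np.random.default_rng(9).normal(2.0, 1.0, size=(10, 4))
        spec = ClassifierSpec("random-forest", seed=7)
        a = train_ensemble(subsets, spec).predict_window_probabilities(X)
        b = train_ensemble(subsets, spec).predict_window_probabilities(X)
        np.testing.assert_array_equal(a, b)

    def test_single_class_subset_is_error(self):
        s = separable_subset()
        s.y[:] = 1
        with pytest.raises(ValueError, match="single class"):
            train_ensemble([s], ClassifierSpec(seed=0))

    def test_mismatched_feature_dims_is_error(self):
        with pytest.raises(ValueError, match="feature dimension"):
            train_ensemble([separable_subset(0, d=4), separable_subset(1, d=6)],
                           ClassifierSpec(seed=0))

    def test_grid_only_for_svm(self):
        with pytest.raises(ValueError):
            ClassifierSpec("random-forest", grid={"C": [1]})

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            ClassifierSpec("perceptron")

    def test_svm_grid_search_trains(self):
        s = separable_subset(n=40)
        spec = ClassifierSpec("svm-rbf", grid={"C": [1.0], "gamma": ["scale"]},
                              seed=0)
        model = train_ensemble([s], spec)
        probs = model.predict_window_probabilities(s.X)
        assert ((probs > 0.5) == s.y).mean() == 1.0


class TestCrossValidate:
    def test_separable_data_perfect_metrics(self):
        subsets = [separable_subset(i, n=60, seed=i) for i in range(2)]
        rep = cross_validate(subsets, ClassifierSpec(seed=0), folds=5)
        assert rep.mcc == pytest.approx(1.0)
        assert rep.auc_roc == pytest.approx(1.0)
        assert rep.accuracy == pytest.approx(1.0)

    def test_permuted_labels_auc_near_half(self):
        # label permutation destroys signal: AUC ~ 0.5 within Monte-Carlo error
        rng = np.random.default_rng(3)
        aucs = []
        for rep in range(50):
            s = separable_subset(n=60, seed=rep)
            rng.shuffle(s.y)
            if s.y[:].sum() in (0, len(s.y)):
                continue
            r = cross_validate([s], ClassifierSpec(seed=rep), folds=5)
            aucs.append(r.auc_roc)
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_too_small_subset_is_fold_error(self):
        s = separable_subset(n=8)
        with pytest.raises(ValueError, match="fewer than 5 folds"):
            cross_validate([s], ClassifierSpec(seed=0), folds=5)

    def test_metric_ranges(self):
        subsets = [separable_subset(i, n=60, seed=i, gap=0.5) for i in range(2)]
        rep = cross_validate(subsets, ClassifierSpec(seed=0))
        for name, v in rep.as_dict().items():
            lo = -1.0 if name == "mcc" else 0.0
            assert lo <= v <= 1.0, name


class TestMccConvention:
    def test_closed_form_agreement(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            y = rng.integers(0, 2, size=50)
            p = rng.integers(0, 2, size=50)
            tp = np.sum((y == 1) & (p == 1))
            tn = np.sum((y == 0) & (p == 0))
            fp = np.sum((y == 0) & (p == 1))
            fn = np.sum((y == 1) & (p == 0))
            denom = np.sqrt(float((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)))
            expected = 0.0 if denom == 0 else (tp * tn - fp * fn) / denom
            assert matthews_corrcoef(y, p) == pytest.approx(expected, abs=1e-12)

    def test_zero_denominator_is_zero(self):
        y = np.array([0, 1, 0, 1])
        p = np.array([1, 1, 1, 1])  # no predicted negatives -> denominator 0
        assert matthews_corrcoef(y, p) == 0.0


class TestPredictBondProbabilities:
    def make_model(self, table, k=4, n_models=3, seed=0):
        rng = np.random.default_rng(seed)
        d = 2 * k * table.d
        subsets = []
        for i in range(n_models):
            X = rng.normal(size=(40, d))
            y = (X[:, 0] > 0).astype(int)
            subsets.append(TrainingSubset(index=i, X=X, y=y))
        return train_ensemble(subsets, ClassifierSpec(seed=seed), table=table)

    def test_terminal_bonds_zero_for_soc8(self, table):
        model = self.make_model(table)
        p = Peptide(id="p", blocks=tuple(np.random.default_rng(0).choice(
            list("ACDEFGHIKLMNPQRSTVWY"), size=100)))
        probs = predict_bond_probabilities(p, model, table)
        assert probs.shape == (99,)
        assert np.all(probs[[0, 1, 2, 96, 97, 98]] == 0.0)
        assert np.all(probs[3:96] > 0.0)

    def test_aggregate_is_mean_of_base_models(self, table):
        model = self.make_model(table, n_models=1)
        clones = EnsembleModel(
            protease_id=model.protease_id, k=model.k,
            table_fingerprint=model.table_fingerprint,
            base_models=model.base_models * 3, spec=model.spec)
        p = Peptide(id="p", blocks=tuple("ACDEFGHIKLMN"))
        a = predict_bond_probabilities(p, model, table)
        b = predict_bond_probabilities(p, clones, table)
        np.testing.assert_allclose(a, b)

    def test_aggregate_bounded_by_base_models(self, table):
        model = self.make_model(table, n_models=4)
        p = Peptide(id="p", blocks=tuple("ACDEFGHIKLMNPQRS"))
        from scissile.descriptors import pattern_features
        from scissile.peptide_core import window_at

        for b in range(3, p.n_bonds - 3):
            X = pattern_features(window_at(p, b, 4).pattern, table)[None, :]
            base = [m.predict_proba(X)[0, 1] for m in model.base_models]
            agg = model.predict_window_probabilities(X)[0]
            assert min(base) - 1e-12 <= agg <= max(base) + 1e-12

    def test_fingerprint_mismatch_rejected(self, table):
        model = self.make_model(table)
        with pytest.raises(ValueError, match="descriptor table"):
            predict_bond_probabilities(
                Peptide(id="p", blocks=tuple("ACDEFGHIKL")), model,
                table.zscaled())

    def test_probabilities_in_unit_interval(self, table):
        model = self.make_model(table)
        p = Peptide(id="p", blocks=tuple("ACDEFGHIKLMNPQRSTVWY"))
        probs = predict_bond_probabilities(p, model, table)
        assert np.all((probs >= 0) & (probs <= 1))


class TestPersistence:
    def test_save_load_roundtrip(self, tmp_path, table):
        model = TestPredictBondProbabilities().make_model(table)
        save_ensemble(model, tmp_path / "bundle")
        loaded = load_ensemble(tmp_path / "bundle")
        p = Peptide(id="p", blocks=tuple("ACDEFGHIKLMNPQ"))
        np.testing.assert_allclose(
            predict_bond_probabilities(p, model, table),
            predict_bond_probabilities(p, loaded, table))
        assert loaded.spec == model.spec
        assert loaded.table_fingerprint == model.table_fingerprint
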