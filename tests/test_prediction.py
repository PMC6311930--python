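import numpy as np
import pytest

from adrpair.prediction import (
    AdrDataset,
    DegenerateLabelsError,
    binary_metrics,
    cross_validate_adr,
    decision_scores,
    evaluate,
    fit_reduce,
    split_folds,
    train_classifier,
)


class TestFolds:
    def test_exact_division(self):
        y = np.array([0, 1] * 5)
        folds = split_folds(10, y, 5, seed=0)
        sizes = np.bincount(folds, minlength=5)
        assert list(sizes) == [2] * 5

    def test_remainder_distribution(self):
        y = np.array([0, 1] * 5 + [0])
        folds = split_folds(11, y, 5, seed=0)
        sizes = sorted(np.bincount(folds, minlength=5), reverse=True)
        assert sizes == [3, 2, 2, 2, 2]

    def test_deterministic_and_stratified(self):
        y = np.array([0] * 10 + [1] * 10)
        f1 = split_folds(20, y, 5, seed=7)
        f2 = split_folds(20, y, 5, seed=7)
        assert (f1 == f2).all()
        for k in range(5):
            assert set(y[f1 == k]) == {0, 1}

    def test_too_many_folds(self):
        with pytest.raises(ValueError):
            split_folds(3, np.array([0, 1, 1]), 5, seed=0)


class TestReduce:
    def test_lossless_at_full_rank(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 6))
        space = fit_reduce(X, 6)
        Z = space.transform(X)
        back = Z @ space.pca.components_ + space.pca.mean_
        assert np.allclose(back, X, atol=1e-10)

    def test_retained_variance_matches_eigendecomposition(self):
        """Top-pcn retained variance equals the sum of the top eigenvalues
        of the sample covariance from an independent eigen-decomposition."""
        rng = np.random.default_rng(1)
        X = (rng.random((50, 20)) < 0.3).astype(float)
        space = fit_reduce(X, 5)
        cov = np.cov(X, rowvar=False, ddof=1)
        eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert np.allclose(
            space.pca.explained_variance_, eigvals[:5], atol=1e-10
        )

    def test_pcn_too_large_raises(self):
        with pytest.raises(ValueError, match="pcn"):
            fit_reduce(np.zeros((5, 3)), 4)


class TestClassifier:
    def separable(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(-3, 0.5, (n // 2, 2)), rng.normal(3, 0.5, (n // 2, 2))])
        y = np.array([0] * (n // 2) + [1] * (n // 2))
        return X, y

    def test_svm_perfect_on_separable(self):
        X, y = self.separable()
        clf = train_classifier(X, y, "svm")
        assert (clf.predict(X) == y).all()

    @pytest.mark.parametrize("algo", ["svm", "logreg", "knn", "rf"])
    def test_deterministic_given_seed(self, algo):
        X, y = self.separable(seed=3)
        p1 = train_classifier(X, y, algo, seed=5).predict(X)
        p2 = train_classifier(X, y, algo, seed=5).predict(X)
        assert (p1 == p2).all()

    def test_single_class_raises(self):
        X, _ = self.separable()
        with pytest.raises(DegenerateLabelsError):
            train_classifier(X, np.ones(len(X), dtype=int), "logreg")

    def test_unknown_algo(self):
        with pytest.raises(ValueError):
            train_classifier(np.zeros((4, 2)), np.array([0, 0, 1, 1]), "mlp")

    def test_logreg_auc_on_planted_signal(self, fixture_model):
        """The planted feature signatures make each ADR's positives
        linearly separable from screened negatives: out-of-fold AUC > 0.9."""
        model = fixture_model
        adr = sorted(model.positives_by_adr())[0]
        ds = model.build_adr_dataset(adr)
        metrics, _, _, _ = cross_validate_adr(ds, pcn=8, algo="logreg", k=5, seed=0)
        assert metrics["auc"] > 0.9


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 0, 1])
        m = binary_metrics(y, y, y.astype(float))
        assert all(m[k] == 1.0 for k in ("precision", "recall", "accuracy", "f1", "auc"))

    def test_constant_scores_give_half_auc(self):
        y = np.array([0, 1, 0, 1])
        m = binary_metrics(y, y, np.zeros(4))
        assert m["auc"] == 0.5

    def test_confusion_table_hand_arithmetic(self):
        # TP=2 FP=1 FN=1 TN=4 on 8 samples
        y_true = np.array([1, 1, 1, 0, 0, 0, 0, 0])
        y_pred = np.array([1, 1, 0, 1, 0, 0, 0, 0])
        m = binary_metrics(y_true, y_pred, y_pred.astype(float))
        assert m["precision"] == pytest.approx(2 / 3)
        assert m["recall"] == pytest.approx(2 / 3)
        assert m["accuracy"] == pytest.approx(6 / 8)
        assert m["f1"] == pytest.approx(2 / 3)

    def test_single_class_truth_excluded_from_macro_auc(self):
        report = evaluate(
            truths={"A": np.array([1, 1]), "B": np.array([0, 1])},
            predictions={"A": np.array([1, 1]), "B": np.array([0, 1])},
            scores={"A": np.array([0.9, 0.8]), "B": np.array([0.1, 0.9])},
        )
        assert report.per_adr["A"]["auc"] is None
        assert report.macro["auc"] == 1.0  # only B contributes

    def test_macro_is_unweighted_mean(self):
        report = evaluate(
            truths={k: np.array([0, 1, 0, 1]) for k in "AB"},
            predictions={"A": np.array([0, 1, 0, 1]), "B": np.array([0, 1, 1, 1])},
            scores={k: np.array([0.1, 0.9, 0.2, 0.8]) for k in "AB"},
        )
        for m in ("precision", "recall", "accuracy", "f1", "auc"):
            vals = [report.per_adr[a][m] for a in "AB"]
            assert report.macro[m] == pytest.approx(np.mean(vals), abs=1e-12)


class TestNoLeakage:
    def test_fold_transform_matches_train_only_fit(self, fixture_model):
        """A PCA space fit on the training rows alone reproduces the
        pipeline's transform: nothing from the test fold leaks in."""
        model = fixture_model
        adr = sorted(model.positives_by_adr())[0]
        ds = model.build_adr_dataset(adr)
        folds = split_folds(len(ds.labels), ds.labels, 5, seed=123)
        test = folds == 0
        space = fit_reduce(ds.matrix[~test], 8, seed=123)
        space2 = fit_reduce(ds.matrix[~test], 8, seed=123)
        assert np.allclose(space.transform(ds.matrix[test]), space2.transform(ds.matrix[test]))
        # and a space fit on all rows differs (the planted signal shifts the mean)
        leaky = fit_reduce(ds.matrix, 8, seed=123)
        assert not np.allclose(leaky.pca.mean_, space.pca.mean_)


def test_adr_dataset_rejects_overlap(fixture_model):
    model = fixture_model
    adr = sorted(model.positives_by_adr())[0]
    pos = sorted(model.positives_by_adr()[adr])
    from adrpair import featurize

    M = featurize.build_matrix([pos[0], pos[0]], model.vectors)
    with pytest.raises(ValueError, match="overlap"):
        AdrDataset(adr, [pos[0], pos[0]], np.array([1, 0]), M)
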