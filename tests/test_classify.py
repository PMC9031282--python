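"""Feature reduction, split protocol, classifier battery and metrics."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist
from sklearn.metrics import silhouette_score

import ramancellmap as rm
from ramancellmap.classify import ClassifierMetrics, FittedFamily, confusion_counts
from ramancellmap.errors import InvalidArgumentError, StratificationError
from ramancellmap.synthdata import NoiseModel


def blob_features(n_per_class, sep, dim=2, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, (n_per_class, dim))
    b = rng.normal(sep, 1, (n_per_class, dim))
    X = np.vstack([a, b])
    y = np.array([rm.CLASS_A] * n_per_class + [rm.CLASS_B] * n_per_class, object)
    return X, y


class TestReduceFeatures:
    def test_pca_lossless_on_low_rank(self, axis_small):
        rng = np.random.default_rng(0)
        basis = rng.normal(size=(2, axis_small.n_channels))
        coords = rng.normal(size=(40, 2))
        s = rm.LabeledSpectraSet(axis_small, coords @ basis + 3.0,
                                 np.array(["A"] * 40, object))
        feats, _ = rm.reduce_features(s, rm.ReductionSpec("pca", 2))
        centered = s.matrix - s.matrix.mean(axis=0)
        assert np.allclose(pdist(feats), pdist(centered), rtol=1e-6)

    def test_pca_15_columns_orthogonal_variance_ordered(self, melanoma_purified_small):
        feats, labels = rm.reduce_features(
            melanoma_purified_small, rm.ReductionSpec("pca", 15)
        )
        assert feats.shape == (melanoma_purified_small.n_spectra, 15)
        cov = np.cov(feats.T)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-8 * np.diag(cov).max()
        assert np.all(np.diff(np.diag(cov)) <= 1e-12)

    def test_tsne_separates_far_clusters(self):
        X, y = blob_features(100, sep=12.0, dim=10, seed=1)
        axis = rm.make_axis(0, 9, 10)
        s = rm.LabeledSpectraSet(axis, X, y)
        emb, labels = rm.reduce_features(s, rm.ReductionSpec("tsne", 2, seed=1))
        assert emb.shape == (200, 2)
        assert silhouette_score(emb, labels.astype(str)) > 0.5

    def test_tsne_deterministic_given_seed(self):
        X, y = blob_features(30, sep=5.0, dim=4, seed=2)
        axis = rm.make_axis(0, 3, 4)
        s = rm.LabeledSpectraSet(axis, X, y)
        e1, _ = rm.reduce_features(s, rm.ReductionSpec("tsne", 2, perplexity=10, seed=3))
        e2, _ = rm.reduce_features(s, rm.ReductionSpec("tsne", 2, perplexity=10, seed=3))
        assert np.array_equal(e1, e2)

    def test_perplexity_validation(self):
        X, y = blob_features(10, sep=1.0, seed=3)
        s = rm.LabeledSpectraSet(rm.make_axis(0, 1, 2), X, y)
        with pytest.raises(InvalidArgumentError):
            rm.reduce_features(s, rm.ReductionSpec("tsne", 2, perplexity=30))


class TestSplitTrainTest:
    def test_published_counts(self):
        """1650 + 880 labeled spectra split 3:1 -> 1898 train / 632 test."""
        n = 1650 + 880
        X = np.zeros((n, 2))
        y = np.array(["A"] * 1650 + ["B"] * 880, object)
        (Xtr, ytr), (Xte, yte) = rm.split_train_test(X, y, rm.SplitSpec(0.75, seed=1))
        assert len(ytr) == 1898
        assert len(yte) == 632

    @pytest.mark.parametrize("n,expected", [(4, 3), (101, 76)])
    def test_round_half_up(self, n, expected):
        X = np.zeros((n, 1))
        y = np.array(["A", "B"] * (n // 2) + ["A"] * (n % 2), object)
        (Xtr, _), (Xte, _) = rm.split_train_test(X, y, rm.SplitSpec(0.75, seed=0))
        assert len(Xtr) == expected
        assert len(Xte) == n - expected

    def test_disjoint_exhaustive_deterministic(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(50, 3))
        y = np.array(["A"] * 25 + ["B"] * 25, object)
        out1 = rm.split_train_test(X, y, rm.SplitSpec(seed=9))
        out2 = rm.split_train_test(X, y, rm.SplitSpec(seed=9))
        assert np.array_equal(out1[0][0], out2[0][0])
        pooled = np.vstack([out1[0][0], out1[1][0]])
        assert np.array_equal(np.sort(pooled, axis=0), np.sort(X, axis=0))

    def test_stratified_proportions(self):
        X = np.zeros((100, 1))
        y = np.array(["A"] * 70 + ["B"] * 30, object)
        (_, ytr), (_, yte) = rm.split_train_test(
            X, y, rm.SplitSpec(0.75, seed=2, stratified=True)
        )
        assert abs((ytr == "A").sum() - 0.75 * 70) <= 1
        assert abs((ytr == "B").sum() - 0.75 * 30) <= 1

    def test_stratification_failure(self):
        X = np.zeros((8, 1))
        y = np.array(["A"] * 7 + ["B"], object)
        with pytest.raises(StratificationError):
            rm.split_train_test(X, y, rm.SplitSpec(0.05, seed=0, stratified=True))


class TestTrainAndEvaluate:
    def test_separable_blobs_all_families_perfect(self):
        X, y = blob_features(40, sep=12.0, seed=5)
        registry = rm.train_models(X, y, rm.CVConfig(folds=5, repeats=1, seed=5))
        assert set(registry) == set(rm.FAMILIES)
        for family, fitted in registry.items():
            assert fitted.cv_accuracy == pytest.approx(1.0), family
        report = rm.evaluate(registry, X, y)
        for family, m in report.metrics.items():
            assert m.accuracy == 1.0, family

    def test_null_features_near_chance(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(200, 5))
        y = np.array([rm.CLASS_A, rm.CLASS_B] * 100, object)
        (tr_X, tr_y), (te_X, te_y) = rm.split_train_test(X, y, rm.SplitSpec(seed=6))
        registry = rm.train_models(
            tr_X, tr_y, rm.CVConfig(folds=5, repeats=1, seed=6),
            families=("lda", "nb", "knn", "svm-linear"),
        )
        report = rm.evaluate(registry, te_X, te_y)
        se = np.sqrt(0.25 / len(te_y))
        for family, m in report.metrics.items():
            assert m.accuracy <= 0.5 + 4 * se, family

    def test_effect_monotonicity(self, axis_small):
        """Median family accuracy grows with the generator's band effect."""
        medians = []
        for ratio in (1.0, 0.75, 0.45):
            effect = rm.EffectVector({c: ratio for c in (749.0, 1003.0, 1451.0)})
            noise = NoiseModel(baseline_scale=2.0, noise_sd=0.2, spike_rate=0, seed=1)
            s = rm.make_labeled_classes(120, 120, effect, noise, seed=10, axis=axis_small)
            purified = rm.purify_set(s)
            feats, labels = rm.reduce_features(purified, rm.ReductionSpec("pca", 10))
            (trX, trY), (teX, teY) = rm.split_train_test(feats, labels,
                                                         rm.SplitSpec(seed=10))
            registry = rm.train_models(
                trX, trY, rm.CVConfig(folds=5, repeats=1, seed=10),
                families=("lda", "qda", "nb", "knn", "svm-linear"),
            )
            report = rm.evaluate(registry, teX, teY)
            medians.append(np.median([m.accuracy for m in report.metrics.values()]))
        assert medians[0] <= medians[1] + 0.05  # null ~ chance, weak above
        assert medians[2] >= medians[1]
        assert medians[2] > medians[0]

    def test_unknown_family(self):
        X, y = blob_features(10, sep=5.0, seed=7)
        with pytest.raises(InvalidArgumentError):
            rm.train_models(X, y, rm.CVConfig(2, 1, 0), families=("frobnicator",))

    def test_single_class_rejected(self):
        X = np.zeros((10, 2))
        y = np.array(["A"] * 10, object)
        with pytest.raises(InvalidArgumentError):
            rm.train_models(X, y, rm.CVConfig(2, 1, 0))


class TestMetrics:
    def test_perfect_predictions(self):
        m = ClassifierMetrics(tp=10, fp=0, tn=10, fn=0)
        assert m.accuracy == m.sensitivity == m.specificity == 1.0

    def test_all_positive_predictor(self):
        # 60:40 positive:negative test set, everything called positive
        y_true = np.array([rm.CLASS_A] * 60 + [rm.CLASS_B] * 40, object)
        y_pred = np.array([rm.CLASS_A] * 100, object)
        tp, fp, tn, fn = confusion_counts(y_true, y_pred, rm.CLASS_A)
        m = ClassifierMetrics(tp, fp, tn, fn)
        assert m.sensitivity == 1.0
        assert m.specificity == 0.0
        assert m.accuracy == pytest.approx(0.6)

    def test_identity_check(self):
        m = ClassifierMetrics(tp=50, fp=5, tn=40, fn=5)
        assert m.accuracy == pytest.approx(0.9)
        assert m.sensitivity == pytest.approx(50 / 55)
        assert m.specificity == pytest.approx(40 / 45)

    def test_metric_identities_from_counts(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            tp, fp, tn, fn = rng.integers(1, 50, 4)
            m = ClassifierMetrics(int(tp), int(fp), int(tn), int(fn))
            assert m.accuracy == (tp + tn) / (tp + tn + fp + fn)
            assert m.sensitivity == tp / (tp + fn)
            assert m.specificity == tn / (tn + fp)
            assert 0 <= m.accuracy <= 1

    def test_report_frame(self):
        report = rm.EvalReport({"lda": ClassifierMetrics(5, 1, 4, 0, 0.9)})
        df = report.to_frame()
        assert df.loc[0, "family"] == "lda"
        assert df.loc[0, "accuracy"] == pytest.approx(0.9)
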