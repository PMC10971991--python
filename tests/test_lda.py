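"""LDA engine: fit geometry, posteriors, LOO evaluation, oracle agreement."""

import numpy as np
import pytest

from metaboselect import LDAModel, classify, classify_batch, fit_lda, loo_evaluate
from metaboselect.cohort import SyntheticConfig, generate_cohort
from metaboselect.lda import DegenerateFoldError, FitError

from conftest import random_three_class


def _two_class_1d(n=10, mean_b=10.0, sd=1.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.concatenate([rng.normal(0, sd, n), rng.normal(mean_b, sd, n)])[:, None]
    y = np.array(["a"] * n + ["b"] * n, dtype=object)
    return X, y


class TestFit:
    def test_two_axes_for_three_classes(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 6))
        y = np.array((["a"] * 10 + ["b"] * 10 + ["c"] * 10), dtype=object)
        model = fit_lda(X, y=y)
        assert model.axes.shape == (6, 2)
        assert model.n_axes == 2

    def test_decision_boundary_at_midpoint(self):
        """Equal-size 1-D classes with symmetric spread: boundary at the midpoint."""
        X = np.array([[-1.0], [0.0], [1.0], [9.0], [10.0], [11.0]])
        y = np.array(["a", "a", "a", "b", "b", "b"], dtype=object)
        model = fit_lda(X, y=y, priors_mode="equal")
        below = classify(model, np.array([4.999]))
        above = classify(model, np.array([5.001]))
        at = classify(model, np.array([5.0]))
        assert below.predicted == "a" and above.predicted == "b"
        assert np.allclose(at.posteriors, [0.5, 0.5])

    def test_pooled_cov_equals_common_within_matrix(self):
        """When every class has the same centered data, pooling returns it."""
        rng = np.random.default_rng(1)
        base = rng.normal(size=(8, 3))
        base -= base.mean(axis=0)
        X = np.vstack([base, base + 5.0, base - 3.0])
        y = np.array(["a"] * 8 + ["b"] * 8 + ["c"] * 8, dtype=object)
        model = fit_lda(X, y=y)
        common = base.T @ base * 3 / (24 - 3)
        assert np.allclose(model.pooled_cov, common)

    def test_priors_modes(self):
        X, y = _two_class_1d(n=5)
        X = np.vstack([X, X[:3] + 20])
        y = np.concatenate([y, np.array(["c"] * 3, dtype=object)])
        prop = fit_lda(X, y=y, priors_mode="proportional")
        eq = fit_lda(X, y=y, priors_mode="equal")
        assert np.allclose(prop.priors, [5 / 13, 5 / 13, 3 / 13])
        assert np.allclose(eq.priors, [1 / 3, 1 / 3, 1 / 3])
        assert abs(prop.priors.sum() - 1) < 1e-12

    def test_errors(self):
        X = np.array([[1.0], [2.0], [3.0]])
        with pytest.raises(FitError):
            fit_lda(X, y=np.array(["a", "a", "b"], dtype=object))  # class of 1
        Xc = np.column_stack([np.arange(8.0), np.ones(8)])
        y = np.array(["a"] * 4 + ["b"] * 4, dtype=object)
        with pytest.raises(FitError, match="constant"):
            fit_lda(Xc, y=y)
        model = fit_lda(*_two_class_1d()[:1], y=_two_class_1d()[1])
        with pytest.raises(ValueError):
            classify(model, np.array([np.nan]))


class TestClassify:
    def test_posteriors_normalized_and_argmax_consistent(self):
        rng = np.random.default_rng(2)
        X, y = random_three_class(rng)
        model = fit_lda(X, y=y)
        post, pred = classify_batch(model, rng.normal(size=(50, X.shape[1])))
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)
        assert all(model.class_names[int(i)] == p for i, p in zip(np.argmax(post, axis=1), pred))

    def test_posterior_near_one_at_isolated_centroid(self):
        """>= 10 Mahalanobis units from all other centroids: posterior ~ 1."""
        X = np.concatenate([np.array([-0.5, 0.0, 0.5]), np.array([19.5, 20.0, 20.5])])[:, None]
        y = np.array(["a"] * 3 + ["b"] * 3, dtype=object)
        model = fit_lda(X, y=y, priors_mode="equal")
        rec = classify(model, model.class_means[0])
        assert rec.posteriors[0] >= 1 - 1e-9

    def test_mahalanobis_affine_invariance(self):
        """Equal-prior predictions are unchanged by any common invertible
        affine re-map of the features."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            X, y = random_three_class(rng, p_max=3)
            p = X.shape[1]
            A = rng.normal(size=(p, p)) + 3 * np.eye(p)
            b = rng.normal(size=p) * 10
            model1 = fit_lda(X, y=y, priors_mode="equal")
            model2 = fit_lda(X @ A + b, y=y, priors_mode="equal")
            Q = rng.normal(size=(25, p))
            _, pred1 = classify_batch(model1, Q)
            _, pred2 = classify_batch(model2, Q @ A + b)
            assert list(pred1) == list(pred2)

    def test_sklearn_posterior_agreement(self):
        sklearn = pytest.importorskip("sklearn")
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis as SkLDA

        rng = np.random.default_rng(4)
        for _ in range(50):
            X, y = random_three_class(rng)
            model = fit_lda(X, y=y, priors_mode="proportional")
            if model.ridge_used:
                continue
            post, pred = classify_batch(model, X)
            sk = SkLDA(solver="svd").fit(X, y.astype(str))
            sk_post = sk.predict_proba(X)
            col = [list(sk.classes_).index(c) for c in model.class_names]
            assert np.abs(post - sk_post[:, col]).max() < 1e-8

    def test_serialization_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        X, y = random_three_class(rng)
        model = fit_lda(X, y=y)
        path = tmp_path / "model.json"
        model.save(path)
        back = LDAModel.load(path)
        assert np.allclose(back.class_means, model.class_means)
        assert np.allclose(back.pooled_cov, model.pooled_cov)
        assert np.allclose(back.axes, model.axes)
        _, p1 = classify_batch(model, X)
        _, p2 = classify_batch(back, X)
        assert list(p1) == list(p2)


class TestLOO:
    def test_separated_classes_reach_full_accuracy(self):
        for seed in range(10):
            X, y = _two_class_1d(n=8, mean_b=10.0, sd=1.0, seed=seed)  # 10 within-SD apart
            report, _ = loo_evaluate(X, y=y)
            assert report.overall_accuracy == 1.0

    def test_null_accuracy_near_majority_baseline(self):
        """Pure-noise features: LOO accuracy concentrates near n_max/N."""
        rng = np.random.default_rng(6)
        y = np.array(["a"] * 31 + ["b"] * 8 + ["c"] * 7, dtype=object)
        accs = []
        for _ in range(200):
            X = rng.normal(size=(46, 1))
            report, _ = loo_evaluate(X, y=y)
            accs.append(report.overall_accuracy)
        assert abs(np.mean(accs) - 31 / 46) < 0.08

    def test_matches_per_fold_refit(self):
        """Fast downdated LOO equals an independent per-fold refit."""
        rng = np.random.default_rng(7)
        for _ in range(30):
            X, y = random_three_class(rng)
            _, records = loo_evaluate(X, y=y)
            for i in range(len(y)):
                mask = np.ones(len(y), bool)
                mask[i] = False
                model = fit_lda(X[mask], y=y[mask], class_order=("a", "b", "c"))
                rec = classify(model, X[i])
                assert rec.predicted == records[i].predicted
                assert np.abs(rec.posteriors - records[i].posteriors).max() < 1e-9

    def test_order_invariance(self):
        rng = np.random.default_rng(8)
        X, y = random_three_class(rng)
        report1, _ = loo_evaluate(X, y=y, class_order=("a", "b", "c"))
        perm = rng.permutation(len(y))
        report2, _ = loo_evaluate(X[perm], y=y[perm], class_order=("a", "b", "c"))
        assert report1.overall_accuracy == report2.overall_accuracy
        assert np.array_equal(report1.confusion, report2.confusion)

    def test_degenerate_fold_error(self):
        X = np.arange(8.0)[:, None]
        y = np.array(["a"] * 6 + ["b"] * 2, dtype=object)
        with pytest.raises(DegenerateFoldError):
            loo_evaluate(X, y=y)
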