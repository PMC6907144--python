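import numpy as np
import pytest

import eigencell as ec
from eigencell.containers import ScoreMatrix
from eigencell.svm import Baseline, rbf_kernel_matrix, train_baseline


def _clouds(rng, n=50, sep=3.0):
    X = np.vstack(
        [rng.normal((-sep, -sep), 1.0, (n, 2)), rng.normal((sep, sep), 1.0, (n, 2))]
    )
    y = np.array([0] * n + [1] * n, dtype=bool)
    return X, y


class TestRbfKernel:
    def test_self_similarity_is_one(self, rng):
        x = rng.normal(size=5)
        assert ec.rbf_kernel(x, x, 2.5) == pytest.approx(1.0)

    def test_closed_form(self):
        assert ec.rbf_kernel([0, 0], [1, 0], 1.0) == pytest.approx(np.exp(-1.0))

    def test_symmetry(self, rng):
        for _ in range(5):
            x, y = rng.normal(size=4), rng.normal(size=4)
            assert ec.rbf_kernel(x, y, 0.7) == pytest.approx(ec.rbf_kernel(y, x, 0.7))

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            ec.rbf_kernel([1, 2], [1, 2, 3], 1.0)

    def test_matrix_agrees_with_scalar(self, rng):
        X, Y = rng.normal(size=(3, 4)), rng.normal(size=(2, 4))
        K = rbf_kernel_matrix(X, Y, 0.3)
        for i in range(3):
            for j in range(2):
                assert K[i, j] == pytest.approx(ec.rbf_kernel(X[i], Y[j], 0.3))


class TestTuneAndTrain:
    def test_separated_clouds_learned(self, rng):
        X, y = _clouds(np.random.default_rng(7))
        model = ec.tune_and_train_svm(X, y, folds=5, seed=7)
        pred = model.decision_function(X) > 0
        assert (pred == y).mean() == 1.0
        assert model.cv_summary["cv_auroc"].max() >= 0.99

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="single class"):
            ec.tune_and_train_svm(rng.normal(size=(10, 2)), np.ones(10, bool))

    def test_same_seed_same_model(self):
        X, y = _clouds(np.random.default_rng(3), sep=1.0)
        a = ec.tune_and_train_svm(X, y, folds=5, seed=5)
        b = ec.tune_and_train_svm(X, y, folds=5, seed=5)
        assert (a.kernel_sigma, a.cost) == (b.kernel_sigma, b.cost)
        np.testing.assert_array_equal(
            a.decision_function(X), b.decision_function(X)
        )

    def test_decision_function_identity_vs_backend(self):
        """The stored support vectors, dual coefficients, and intercept must
        reproduce the trainer's decision values."""
        from sklearn.svm import SVC

        X, y = _clouds(np.random.default_rng(1), sep=1.5)
        model = ec.tune_and_train_svm(X, y, folds=5, seed=1)
        clf = SVC(C=model.cost, kernel="rbf", gamma=model.kernel_sigma)
        clf.fit(X, y)
        np.testing.assert_allclose(
            model.decision_function(X), clf.decision_function(X), atol=1e-8
        )

    def test_folds_reduced_with_warning(self):
        X, y = _clouds(np.random.default_rng(2), n=6)
        with pytest.warns(UserWarning, match="reducing folds"):
            ec.tune_and_train_svm(X, y, folds=10, seed=0)


class TestPlattScaling:
    def test_sigmoid_at_zero(self):
        assert 1 / (1 + np.exp(-1 * 0 + 0)) == pytest.approx(0.5)
        # fitted on symmetric data, f=0 must map near 0.5
        rng = np.random.default_rng(0)
        f = np.concatenate([rng.normal(-1, 0.3, 100), rng.normal(1, 0.3, 100)])
        y = np.array([False] * 100 + [True] * 100)
        A, B = ec.fit_platt_scaling(f, y)
        assert 1 / (1 + np.exp(B)) == pytest.approx(0.5, abs=0.05)

    def test_closed_form_probability(self):
        assert 1 / (1 + np.exp(-2 * 1 + 0)) == pytest.approx(0.8808, abs=1e-4)

    def test_separated_decisions_calibrate_sharply(self, rng):
        f = np.concatenate([rng.uniform(-3, -1, 200), rng.uniform(1, 3, 200)])
        y = np.array([False] * 200 + [True] * 200)
        A, B = ec.fit_platt_scaling(f, y)
        p = 1 / (1 + np.exp(A * f + B))
        assert np.all(p[y] > 0.9) and np.all(p[~y] < 0.1)

    def test_matches_independent_ml_fit(self, rng):
        from sklearn.calibration import _sigmoid_calibration

        f = rng.normal(size=80)
        y = f + rng.normal(0, 1.0, 80) > 0
        A, B = ec.fit_platt_scaling(f, y)
        a_ref, b_ref = _sigmoid_calibration(f, y.astype(float))
        assert A == pytest.approx(a_ref, abs=1e-5)
        assert B == pytest.approx(b_ref, abs=1e-5)

    def test_probability_monotone_in_decision_value(self, rng):
        f = rng.normal(size=60)
        y = f + rng.normal(0, 0.5, 60) > 0
        A, B = ec.fit_platt_scaling(f, y)
        grid = np.linspace(-3, 3, 50)
        p = 1 / (1 + np.exp(A * grid + B))
        assert np.all(np.diff(p) > 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ec.fit_platt_scaling([1.0, 2.0], [True, True])


class TestSmote:
    def test_synthetic_point_on_segment(self):
        X = np.array([[0.0, 0.0], [2.0, 2.0], [5.0, 5.0], [6.0, 6.0], [7.0, 7.0]])
        y = np.array(["min", "min", "maj", "maj", "maj"], dtype=object)
        Xb, yb = ec.smote_oversample(X, y, k_neighbors=1, seed=0)
        new = Xb[len(X):]
        assert new.shape[0] == 1
        # point lies on the segment between the two minority points
        lam = new[0, 0] / 2.0
        assert 0 <= lam <= 1 and new[0, 1] == pytest.approx(new[0, 0])

    def test_balanced_input_unchanged(self, rng):
        X = rng.normal(size=(10, 3))
        y = np.array(["a"] * 5 + ["b"] * 5, dtype=object)
        Xb, yb = ec.smote_oversample(X, y, seed=1)
        np.testing.assert_array_equal(Xb, X)

    def test_imbalance_corrected_and_deterministic(self, rng):
        X = rng.normal(size=(60, 4))
        y = np.array(["min"] * 10 + ["maj"] * 50, dtype=object)
        X1, y1 = ec.smote_oversample(X, y, seed=42)
        X2, y2 = ec.smote_oversample(X, y, seed=42)
        np.testing.assert_array_equal(X1, X2)
        counts = {c: (y1 == c).sum() for c in ("min", "maj")}
        assert 0.9 <= counts["min"] / counts["maj"] <= 1.1
        np.testing.assert_array_equal(X1[:60], X)

    def test_synthetic_points_are_convex_combinations(self, rng):
        X = rng.normal(size=(30, 3))
        y = np.array(["min"] * 8 + ["maj"] * 22, dtype=object)
        Xb, yb = ec.smote_oversample(X, y, seed=3)
        minority = X[:8]
        for p in Xb[30:]:
            # distance from p to the nearest segment between two originals
            best = np.inf
            for i in range(8):
                for j in range(8):
                    if i == j:
                        continue
                    d = minority[j] - minority[i]
                    t = np.clip(np.dot(p - minority[i], d) / np.dot(d, d), 0, 1)
                    best = min(best, np.linalg.norm(p - (minority[i] + t * d)))
            assert best < 1e-10

    def test_minority_of_one_rejected(self):
        X = np.zeros((4, 2))
        y = np.array(["min", "maj", "maj", "maj"], dtype=object)
        with pytest.raises(ValueError, match="at least 2"):
            ec.smote_oversample(X, y)


class TestOneVsAll:
    def test_bundle_structure(self, trained_bundle):
        assert len(trained_bundle.models) == 3
        assert len(trained_bundle.selections) == 3
        assert sorted(trained_bundle.class_names) == ["alpha", "beta", "delta"]

    def test_support_vectors_match_feature_dims(self, trained_bundle):
        for c, model in trained_bundle.models.items():
            sel = trained_bundle.selections[c]
            assert model.support_vectors.shape[1] == sel.pc_indices.size

    def test_binary_collapse_complement(self, flat_dataset):
        keep = np.isin(flat_dataset.labels, ["alpha", "beta"])
        counts = flat_dataset.counts.subset_cells(keep)
        cfg = ec.PipelineConfig(folds=5, seed=2, extra={"binary_collapse": True})
        bundle = ec.train_model(counts, flat_dataset.labels[keep], cfg)
        assert len(bundle.models) == 1
        probs = ec.predict_probabilities(bundle, counts)
        np.testing.assert_allclose(
            probs.probabilities.sum(axis=1), 1.0, atol=1e-12
        )


class TestBaselines:
    def test_intercept_only_constant_decision(self, rng):
        model = train_baseline("intercept_only", {})
        dec = model.decision_function(rng.normal(size=(30, 4)))
        assert np.all(dec == dec[0])
        y = np.array([True] * 10 + [False] * 20)
        assert ec.auroc(dec, y) == 0.5

    def test_mean_logcpm_detects_global_shift(self, rng):
        from eigencell.containers import CountMatrix

        # class A cells express every gene ~2x higher relative to a spike
        # gene, shifting the per-cell mean log2 CPM
        n, m = 60, 40
        base = rng.integers(20, 40, size=(n, m))
        base[:30, : m - 1] *= 4  # class A: most genes up, spike gene not
        counts = CountMatrix(
            base,
            np.array([f"c{i}" for i in range(n)], dtype=object),
            np.array([f"g{j}" for j in range(m - 1)] + ["spike"], dtype=object),
        )
        labels = np.array(["A"] * 30 + ["B"] * 30, dtype=object)
        log = ec.normalize_log_cpm(counts)
        model = train_baseline(
            "mean_logcpm",
            {"log_matrix": log, "labels": labels, "positive_class": "A"},
            {"folds": 5, "seed": 0},
        )
        feats = log.dense().mean(axis=1, keepdims=True)
        assert ec.auroc(model.decision_function(feats), labels == "A") > 0.9

    def test_de_genes_refuses_null_data(self, rng):
        from eigencell.containers import CountMatrix

        n, m = 40, 30
        counts = CountMatrix(
            rng.poisson(20, size=(n, m)),
            np.array([f"c{i}" for i in range(n)], dtype=object),
            np.array([f"g{j}" for j in range(m)], dtype=object),
        )
        labels = np.array(["A"] * 20 + ["B"] * 20, dtype=object)
        log = ec.normalize_log_cpm(counts)
        with pytest.raises(ValueError, match="differentially expressed"):
            train_baseline(
                "de_genes",
                {"log_matrix": log, "labels": labels, "positive_class": "A"},
            )

    def test_unit_coefficients_decision(self, rng):
        scores = rng.normal(size=(20, 3))
        model = train_baseline(
            "unit_coefficients",
            {"scores": scores, "labels": np.array(["A"] * 10 + ["B"] * 10), "positive_class": "A"},
        )
        dec = model.decision_function(scores)
        np.testing.assert_allclose(dec, scores.sum(axis=1) - scores.sum(axis=1).mean(), atol=1e-12)
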