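"""Origin classifiers, cross-validation, and multinomial composition tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from cafkit.origin import (
    KNNReference,
    assign_origin,
    composition_multinomial_test,
    cross_validate,
    multinomial_lrt,
    train_origin_model,
)
from cafkit.preprocess import filter_min_genes, normalize_log
from cafkit.simulate import simulate_reference_atlas

from conftest import make_adata


@pytest.fixture(scope="module")
def atlas(small_config, small_qc):
    adata, truth = simulate_reference_atlas(small_config, n_cells_per_pop=150)
    norm = normalize_log(filter_min_genes(adata, small_qc), small_qc)
    features = [
        g for g in dict.fromkeys(truth.marker_table["gene"]) if g in norm.var_names
    ]
    return norm, norm.obs["population"].to_numpy(), features


class TestKNN:
    def test_matches_sklearn_on_tie_free_data(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(90, 5))
        y = np.repeat(["a", "b", "c"], 30)
        X[y == "b"] += 3
        X[y == "c"] -= 3
        Q = rng.normal(size=(40, 5)) + rng.choice([-3, 0, 3], size=(40, 1))
        ours = KNNReference(k=5).fit(X, y).predict(Q)
        from sklearn.neighbors import KNeighborsClassifier

        ref = KNeighborsClassifier(n_neighbors=5).fit(X, y).predict(Q)
        np.testing.assert_array_equal(ours, ref)

    def test_singleton_classes_k1_returns_exact_match(self):
        X = np.eye(3)
        y = np.array(["a", "b", "c"])
        model = KNNReference(k=1).fit(X, y)
        np.testing.assert_array_equal(model.predict(X), y)

    def test_vote_tie_goes_to_smallest_class_index(self):
        X = np.array([[0.0], [2.0]])
        y = np.array(["z", "a"])  # classes sorted: a < z
        pred = KNNReference(k=2).fit(X, y).predict(np.array([[1.0]]))
        assert pred[0] == "a"

    def test_k_larger_than_training_set_clipped_with_warning(self):
        X = np.random.default_rng(1).normal(size=(50, 3))
        y = np.repeat(["a", "b"], 25)
        with pytest.warns(UserWarning, match="clipping"):
            model = KNNReference(k=100).fit(X, y)
        assert model.k_eff_ == 50


class TestTraining:
    @pytest.mark.parametrize("engine", ["random_forest", "knn", "svm_linear"])
    def test_planted_atlas_training_accuracy(self, atlas, engine):
        norm, labels, features = atlas
        model = train_origin_model(
            norm, labels, engine=engine, features=features, seed=0
        )
        acc = float(np.mean(model.predict(norm) == labels))
        assert acc >= 0.99

    def test_unseen_feature_at_prediction_rejected(self, atlas):
        norm, labels, features = atlas
        model = train_origin_model(norm, labels, engine="knn", features=features)
        query = make_adata(np.ones((2, 3)), genes=["x1", "x2", "x3"])
        with pytest.raises(KeyError, match="absent"):
            model.predict(query)

    def test_class_with_one_cell_rejected(self):
        adata = make_adata(np.ones((3, 4)))
        with pytest.raises(ValueError, match="at least 2"):
            train_origin_model(
                adata, ["a", "a", "b"], engine="random_forest"
            )


class TestCrossValidation:
    def test_fixed_seed_reproduces_split_sequence(self, atlas):
        norm, labels, features = atlas
        a = cross_validate(norm, labels, "knn", features, repeats=3, seed=42)
        b = cross_validate(norm, labels, "knn", features, repeats=3, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_shuffled_labels_fall_to_chance(self, atlas):
        norm, labels, features = atlas
        rng = np.random.default_rng(0)
        shuffled = rng.permutation(labels)
        cv = cross_validate(norm, shuffled, "knn", features, repeats=10, seed=1)
        n_test = 3 * 15 * 10  # 10% per class per repeat
        sd = np.sqrt((1 / 3) * (2 / 3) / n_test)
        assert abs(cv["accuracy"].mean() - 1 / 3) < 3 * sd + 0.02

    def test_separable_atlas_high_accuracy(self, atlas):
        norm, labels, features = atlas
        cv = cross_validate(norm, labels, "knn", features, repeats=5, seed=2)
        assert cv["accuracy"].mean() >= 0.95
        assert {"accuracy_HSC-like", "accuracy_SAMes-like"} <= set(cv.columns)


class TestAssignment:
    def test_reference_cells_assigned_to_own_class(self, atlas):
        norm, labels, features = atlas
        model = train_origin_model(norm, labels, "knn", features)
        query = norm[labels == "VSMC-like"].copy()
        query.obs["sub"] = "popX"
        table, preds = assign_origin(model, query)
        assert table.loc["popX", "VSMC-like"] == 1.0

    def test_rows_sum_to_one(self, atlas, caf_small, small_qc):
        norm, labels, features = atlas
        adata, _ = caf_small
        caf_norm = normalize_log(filter_min_genes(adata, small_qc), small_qc)
        models = {
            e: train_origin_model(norm, labels, e, features, seed=0)
            for e in ("random_forest", "knn")
        }
        table, preds = assign_origin(models, caf_norm)
        class_cols = [c for c in table.columns if c != "n"]
        np.testing.assert_allclose(table[class_cols].sum(axis=1), 1.0, atol=1e-9)
        assert "consensus" in preds.columns

    def test_planted_origins_recovered(self, atlas, caf_small, small_qc):
        norm, labels, features = atlas
        adata, _ = caf_small
        caf_norm = normalize_log(filter_min_genes(adata, small_qc), small_qc)
        model = train_origin_model(norm, labels, "knn", features, seed=0)
        table, _ = assign_origin(model, caf_norm)
        assert table.loc["CP-CAF", "SAMes-like"] >= 0.9
        assert table.loc["CS-CAF", "SAMes-like"] >= 0.9
        assert table.loc["Ctr-CAF-I", "VSMC-like"] >= 0.9
        assert table.loc["Ctr-CAF-II", "HSC-like"] >= 0.9

    def test_empty_population_omitted_with_warning(self, atlas):
        norm, labels, features = atlas
        model = train_origin_model(norm, labels, "knn", features)
        query = norm[:10].copy()
        query.obs["sub"] = pd.Categorical(
            ["popA"] * 10, categories=["popA", "popB"]
        )
        with pytest.warns(UserWarning, match="omitted"):
            table, _ = assign_origin(model, query)
        assert "popB" not in table.index


class TestMultinomial:
    def test_exact_tail_of_degenerate_table(self):
        # all 10 counts in one of three equiprobable cells: the only tables
        # with an LLR at least as large are the three degenerate ones
        p = multinomial_lrt([10, 0, 0], [1 / 3, 1 / 3, 1 / 3])
        assert p == pytest.approx(3 * (1 / 3) ** 10, rel=1e-9)

    def test_identical_proportions_large_n_p_near_one(self):
        table = pd.DataFrame([[400, 300, 300], [4000, 3000, 3000]])
        res = composition_multinomial_test(table)
        assert res["p"].iloc[0] > 0.99

    def test_exact_enumeration_close_to_chi2_at_moderate_n(self):
        counts = [60, 30, 30]
        probs = [0.45, 0.3, 0.25]
        exact = multinomial_lrt(counts, probs, exact=True)
        approx = multinomial_lrt(counts, probs, exact=False)
        assert abs(exact - approx) / approx < 0.10

    def test_brute_force_outcome_enumeration_oracle(self):
        # independent oracle: walk every outcome of n=6, k=3 directly
        import itertools
        from math import factorial

        counts, probs = [4, 1, 1], np.array([0.5, 0.25, 0.25])

        def llr(c):
            c = np.asarray(c)
            n = c.sum()
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(c > 0, c * np.log((c / n) / probs), 0.0)
            return 2 * t.sum()

        obs = llr(counts)
        total = 0.0
        for a in range(7):
            for b in range(7 - a):
                c = 6 - a - b
                if llr([a, b, c]) >= obs - 1e-12:
                    coef = factorial(6) / (
                        factorial(a) * factorial(b) * factorial(c)
                    )
                    total += coef * probs[0] ** a * probs[1] ** b * probs[2] ** c
        assert multinomial_lrt(counts, probs, exact=True) == pytest.approx(
            total, rel=1e-9
        )

    def test_zero_total_group_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            multinomial_lrt([0, 0, 0], [1 / 3, 1 / 3, 1 / 3])
        with pytest.raises(ValueError):
            composition_multinomial_test(pd.DataFrame([[0, 0], [1, 1]]))
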