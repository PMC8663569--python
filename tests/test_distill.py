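"""PCA candidates, sparse PLS-DA, BER cross-validation and the elbow."""

import numpy as np
import pandas as pd
import pytest

from becdistill.distill import (
    FeatureSelectionTrace,
    balanced_error_rate,
    cv_ber,
    eigenvector_gene_lists,
    n_pcs_for_variance,
    pca_loadings,
    predict_clusters,
    select_elbow,
    train_splsda,
)
from becdistill.io import ExpressionMatrix


def _expr(x: np.ndarray) -> ExpressionMatrix:
    return ExpressionMatrix(
        pd.DataFrame(
            x,
            index=[f"g{i}" for i in range(x.shape[0])],
            columns=[f"s{i}" for i in range(x.shape[1])],
        )
    )


@pytest.fixture
def separable():
    """Two classes split cleanly along genes g0/g1."""
    rng = np.random.default_rng(2)
    n = 40
    labels = np.repeat([1, 2], n // 2)
    x = rng.normal(0, 0.2, (10, n))
    x[0] += np.where(labels == 2, 3.0, 0.0)
    x[1] -= np.where(labels == 2, 3.0, 0.0)
    return _expr(x), labels


class TestPca:
    def test_single_varying_gene_dominates_pc1(self):
        rng = np.random.default_rng(1)
        x = np.full((5, 30), 2.0)  # constant background
        x[2] = rng.normal(0, 5.0, 30)
        loadings, _ = pca_loadings(_expr(x))
        assert abs(loadings.loc["g2", "PC1"]) > 0.99

    def test_explained_variance_conserved(self, toy_matrix):
        _, explained = pca_loadings(toy_matrix)
        x = toy_matrix.values.T
        xs = (x - x.mean(0)) / x.std(0)
        total = xs.var(axis=0, ddof=1).sum()
        assert explained.sum() == pytest.approx(total, abs=1e-8)

    def test_sign_convention_reproducible(self, toy_matrix):
        l1, _ = pca_loadings(toy_matrix)
        l2, _ = pca_loadings(toy_matrix)
        pd.testing.assert_frame_equal(l1, l2)
        for pc in l1.columns:
            assert l1[pc].to_numpy()[np.argmax(np.abs(l1[pc].to_numpy()))] > 0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pca_loadings(_expr(np.full((4, 6), 3.0)))


class TestEigenvectorLists:
    def _loadings(self):
        return pd.DataFrame(
            {
                "PC1": [0.9, 0.1, 0.05, 0.02],
                "PC2": [0.8, 0.3, 0.1, 0.01],
            },
            index=["g0", "g1", "g2", "g3"],
        )

    def test_union_collapses_duplicates(self):
        lists = eigenvector_gene_lists(self._loadings(), [1], n_pcs=2)
        assert lists == [(1, ["g0"])]

    def test_full_grid_value_returns_all(self):
        lists = eigenvector_gene_lists(self._loadings(), [4], n_pcs=2)
        assert sorted(lists[0][1]) == ["g0", "g1", "g2", "g3"]

    def test_oversized_grid_value_capped(self, caplog):
        with caplog.at_level("WARNING"):
            lists = eigenvector_gene_lists(self._loadings(), [10], n_pcs=1)
        assert len(lists[0][1]) == 4

    def test_too_many_pcs_rejected(self):
        with pytest.raises(ValueError, match="n_pcs"):
            eigenvector_gene_lists(self._loadings(), [1], n_pcs=5)

    def test_planted_genes_recovered_from_cohort(self, default_cohort):
        _, expr, _, truth = default_cohort
        sub = expr.subset_genes(sorted(truth.all_de_genes))
        loadings, explained = pca_loadings(sub)
        lists = eigenvector_gene_lists(loadings, [10], n_pcs=3)
        recovered = set(lists[0][1]) & truth.all_de_genes
        assert len(recovered) >= 24  # >= 80% of a 30-gene-scale union


class TestNPcs:
    def test_variance_fraction_rule(self):
        ev = np.array([6.0, 2.0, 1.0, 0.5, 0.5])
        assert n_pcs_for_variance(ev, fraction=0.8) == 2
        assert n_pcs_for_variance(ev, fraction=0.99, cap=3) == 3


class TestSplsda:
    def test_separable_classes_zero_training_ber(self, separable):
        expr, labels = separable
        model = train_splsda(expr, labels, expr.gene_ids, n_components=1)
        pred = model.predict(expr.values.T, standardize="train")
        assert balanced_error_rate(labels, pred) == 0.0

    def test_permuted_labels_near_chance(self, separable):
        expr, labels = separable
        rng = np.random.default_rng(5)
        perm = rng.permutation(labels)
        mean_ber, _ = cv_ber(expr, perm, expr.gene_ids, 1, folds=4, repeats=3, seed=0)
        assert abs(mean_ber - 0.5) < 0.15  # (k-1)/k for k=2

    def test_serialization_round_trip_identical_predictions(self, separable, tmp_path):
        expr, labels = separable
        model = train_splsda(expr, labels, expr.gene_ids, n_components=1)
        path = tmp_path / "model.json"
        model.to_json(path)
        from becdistill.distill import SparseDAModel

        back = SparseDAModel.from_json(path)
        x = expr.values.T
        assert np.array_equal(model.predict(x), back.predict(x))

    def test_singleton_class_rejected(self, separable):
        expr, labels = separable
        labels = labels.copy()
        labels[0] = 99
        with pytest.raises(ValueError, match="single sample"):
            train_splsda(expr, labels, expr.gene_ids, 1)

    def test_loadings_sparse_under_keepx(self, separable):
        expr, labels = separable
        model = train_splsda(expr, labels, expr.gene_ids, 1, keepx=[2])
        w = model.weights[:, 0]
        assert (w != 0).sum() <= 2
        assert np.linalg.norm(w) == pytest.approx(1.0)

    def test_prediction_ignores_non_model_genes(self, separable):
        expr, labels = separable
        model = train_splsda(expr, labels, ["g0", "g1"], n_components=1)
        pred1 = predict_clusters(model, expr, standardize="train")
        shuffled = expr.data.copy()
        rng = np.random.default_rng(3)
        for g in expr.gene_ids:
            if g not in ("g0", "g1"):
                shuffled.loc[g] = rng.permutation(shuffled.loc[g].to_numpy())
        pred2 = predict_clusters(model, ExpressionMatrix(shuffled), standardize="train")
        assert pred1.labels == pred2.labels

    def test_single_sample_prediction(self, separable):
        expr, labels = separable
        model = train_splsda(expr, labels, expr.gene_ids, 1)
        one = ExpressionMatrix(expr.data.iloc[:, [0]])
        assign = predict_clusters(model, one, standardize="train")
        assert len(assign.labels) == 1

    def test_missing_genes_listed(self, separable):
        expr, labels = separable
        model = train_splsda(expr, labels, expr.gene_ids, 1)
        small = ExpressionMatrix(expr.data.iloc[:3])
        with pytest.raises(KeyError, match="g3"):
            predict_clusters(model, small)


class TestBer:
    def test_confusion_hand_example(self):
        y_true = np.array(["A"] * 10 + ["B"] * 2)
        y_pred = np.array(["A"] * 8 + ["B"] * 2 + ["B", "A"])
        assert balanced_error_rate(y_true, y_pred) == pytest.approx(0.35)

    def test_perfect_classifier_zero(self):
        y = np.array([1, 2, 3, 1, 2, 3])
        assert balanced_error_rate(y, y) == 0.0

    def test_invariant_to_class_imbalance(self):
        y_true = np.array([1] * 4 + [2] * 4)
        y_dup = np.array([1] * 40 + [2] * 4)
        assert balanced_error_rate(y_true, y_true) == balanced_error_rate(y_dup, y_dup)

    def test_cv_reproducible(self, separable):
        expr, labels = separable
        r1 = cv_ber(expr, labels, expr.gene_ids, 1, folds=4, repeats=2, seed=3)
        r2 = cv_ber(expr, labels, expr.gene_ids, 1, folds=4, repeats=2, seed=3)
        assert r1 == r2

    def test_stratification_guard(self, separable):
        expr, labels = separable
        with pytest.raises(ValueError, match="stratification"):
            cv_ber(expr, labels, expr.gene_ids, 1, folds=30)


class TestElbow:
    def _trace(self, bers, sds=None, sizes=None):
        n = len(bers)
        sizes = sizes or [5 * (i + 1) for i in range(n)]
        sds = sds or [0.02] * n
        return FeatureSelectionTrace(
            pd.DataFrame(
                {
                    "n_per_pc": sizes,
                    "n_genes": sizes,
                    "mean_ber": bers,
                    "sd_ber": sds,
                }
            )
        )

    def test_plateau_start_chosen(self):
        trace = self._trace([0.5, 0.3, 0.12, 0.10, 0.10, 0.10])
        assert select_elbow(trace, tolerance=0.02) == 15

    def test_flat_curve_returns_smallest_with_warning(self):
        trace = self._trace([0.2] * 5)
        with pytest.warns(UserWarning, match="no curvature"):
            assert select_elbow(trace) == 5

    def test_monotone_decreasing_returns_minimum(self):
        trace = self._trace([0.5, 0.42, 0.35, 0.29, 0.24])
        assert select_elbow(trace, tolerance=0.0) == 25

    def test_too_few_points_rejected(self):
        trace = self._trace([0.5, 0.3, 0.1])
        with pytest.raises(ValueError, match="5 grid points"):
            select_elbow(trace)

    def test_ber_bounds_validated(self):
        with pytest.raises(ValueError, match="BER"):
            self._trace([0.5, 1.4, 0.2, 0.2, 0.2])
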