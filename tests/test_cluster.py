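"""Lloyd k-means, v-fold cross-validated cost and cluster-count selection."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mcakm import synthetic
from mcakm.cluster import (
    ClusteringConfig,
    classify_categories,
    cost_table,
    kmeans,
    select_k,
    vfold_cost,
)


from _oracles import exhaustive_best_cost


class TestKmeans:
    def test_k_equals_distinct_points_costs_zero(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        sol = kmeans(pts, 3, ClusteringConfig(seed=0))
        assert sol.within_cost == 0.0
        assert len(set(sol.assignment)) == 3

    def test_k1_closed_form(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(12, 3))
        sol = kmeans(pts, 1, ClusteringConfig(seed=0))
        centroid = pts.mean(axis=0)
        assert np.allclose(sol.centers[0], centroid)
        expected = np.linalg.norm(pts - centroid, axis=1).mean()
        assert sol.within_cost == pytest.approx(expected)

    def test_two_triads_recovered_exactly(self):
        triad1 = np.array([[0, 0], [1, 0], [0, 1]], dtype=float)
        triad2 = triad1 + 10.0
        pts = np.vstack([triad1, triad2])
        sol = kmeans(pts, 2, ClusteringConfig(seed=3, n_restarts=10))
        assert sol.within_cost == pytest.approx(exhaustive_best_cost(pts, 2))
        assert len(set(sol.assignment[:3])) == 1 and len(set(sol.assignment[3:])) == 1

    @pytest.mark.parametrize("metric", ["squared", "distance"])
    @pytest.mark.parametrize("k", [2, 3])
    def test_matches_exhaustive_on_random_points(self, k, metric):
        rng = np.random.default_rng(17)
        pts = rng.normal(size=(7, 2))
        sol = kmeans(pts, k, ClusteringConfig(seed=1, n_restarts=50, metric=metric))
        assert sol.within_cost == pytest.approx(exhaustive_best_cost(pts, k, metric), abs=1e-9)

    def test_k_above_distinct_points_rejected(self):
        pts = np.zeros((5, 2))
        with pytest.raises(ValueError, match="distinct"):
            kmeans(pts, 2, ClusteringConfig(seed=0))

    def test_seed_determinism(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(30, 2))
        a = kmeans(pts, 4, ClusteringConfig(seed=42))
        b = kmeans(pts, 4, ClusteringConfig(seed=42))
        assert np.array_equal(a.assignment, b.assignment)
        assert np.allclose(a.centers, b.centers)

    def test_every_point_assigned_to_nearest_center(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(40, 2))
        sol = kmeans(pts, 5, ClusteringConfig(seed=8))
        dist = np.linalg.norm(pts[:, None] - sol.centers[None], axis=2)
        assert np.array_equal(sol.assignment, dist.argmin(axis=1))


class TestVfoldCost:
    def test_leave_one_out_fold_arithmetic(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(8, 2)) * 3
        cv, fold_costs = vfold_cost(pts, 2, ClusteringConfig(seed=0, v=8))
        assert len(fold_costs) == 8
        assert cv == pytest.approx(fold_costs.mean())

    def test_fold_coverage_partition(self):
        from mcakm.cluster import _fold_indices

        folds = _fold_indices(33, 5, seed=7)
        flat = np.concatenate(folds)
        assert len(flat) == 33 and set(flat) == set(range(33))

    def test_duplicated_dataset_cv_close_to_within(self):
        pts, _ = synthetic.generate_blobs(24, 3, seed=4)
        doubled = np.vstack([pts, pts])
        config = ClusteringConfig(seed=2, v=5)
        cv, _ = vfold_cost(doubled, 3, config)
        within = kmeans(doubled, 3, config).within_cost
        assert cv == pytest.approx(within, rel=0.10)

    def test_three_blobs_much_cheaper_at_true_k(self):
        pts, _ = synthetic.generate_blobs(45, 3, seed=11)
        config = ClusteringConfig(seed=5)
        cv3, _ = vfold_cost(pts, 3, config)
        cv2, _ = vfold_cost(pts, 2, config)
        assert cv3 < 0.5 * cv2

    def test_too_few_training_points_for_k(self):
        pts = np.arange(6, dtype=float).reshape(-1, 1)
        with pytest.raises(ValueError, match="smaller k"):
            vfold_cost(pts, 5, ClusteringConfig(seed=0, v=3))


class TestSelectK:
    @pytest.mark.parametrize("ktrue", [2, 3, 5])
    def test_planted_blob_count_recovered(self, ktrue):
        pts, _ = synthetic.generate_blobs(60, ktrue, seed=ktrue)
        result = select_k(pts, ClusteringConfig(seed=ktrue, n_restarts=8))
        assert result.optimal_k == ktrue
        assert not result.fallback

    def test_identical_points_with_jitter_plateau_from_start(self):
        # nearly coincident points: costs flat in k, so parsimony keeps k_min
        rng = np.random.default_rng(1)
        pts = np.ones((20, 2)) + rng.normal(scale=1e-6, size=(20, 2))
        result = select_k(pts, ClusteringConfig(seed=1))
        assert result.optimal_k == 2

    def test_fold_significance_rule_on_blobs(self):
        pts, _ = synthetic.generate_blobs(60, 3, seed=9)
        result = select_k(
            pts, ClusteringConfig(seed=9, selection_rule="fold_significance", n_restarts=8)
        )
        assert result.optimal_k == 3

    def test_fallback_flag_when_no_plateau(self):
        # strong 12-blob structure scanned only up to k=6: every split helps
        pts, _ = synthetic.generate_blobs(120, 12, separation=8.0, seed=3)
        result = select_k(pts, ClusteringConfig(seed=3, k_min=2, k_max=6))
        assert result.fallback
        assert any("warning" in t for t in result.trace)

    def test_trace_records_costs_for_every_k(self):
        pts, _ = synthetic.generate_blobs(40, 2, seed=6)
        result = select_k(pts, ClusteringConfig(seed=6, k_max=5))
        ks = [t["k"] for t in result.trace if "k" in t]
        assert ks == [2, 3, 4, 5]
        table = cost_table(result)
        assert table.selected.sum() == 1

    def test_infeasible_range_rejected(self):
        pts = np.zeros((5, 2))
        with pytest.raises(ValueError, match="infeasible"):
            select_k(pts, ClusteringConfig(seed=0))


class TestClassifyCategories:
    def _frame(self, coords, labels):
        idx = pd.MultiIndex.from_tuples(labels, names=["variable", "level"])
        return pd.DataFrame(coords, index=idx)

    def test_strength_one_pair_lands_in_same_cluster(self):
        spec = synthetic.cohort_preset("table1_anxiety_osteoporosis", seed=2, strength=1.0)
        from mcakm import mca

        model = mca.fit_mca(mca.encode_indicator(synthetic.generate_cohort(spec)))
        G = mca.coordinates_frame(model)
        result = select_k(G, ClusteringConfig(seed=2))
        table = classify_categories(G, result.solutions[result.optimal_k])
        t = table.set_index(["variable", "level"]).cluster
        assert t[("anxiety", "Yes")] == t[("osteoporosis", "Yes")]

    def test_single_cluster_labels_all_one(self):
        G = self._frame(np.random.default_rng(0).normal(size=(4, 2)),
                        [("a", "x"), ("a", "y"), ("b", "x"), ("b", "y")])
        sol = kmeans(G, 1, ClusteringConfig(seed=0))
        table = classify_categories(G, sol)
        assert set(table.cluster) == {1}

    def test_identical_rows_share_cluster_and_numbering_is_dense(self):
        coords = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0], [5.0, 5.0]])
        G = self._frame(coords, [("a", "x"), ("b", "x"), ("a", "y"), ("b", "y")])
        sol = kmeans(G, 2, ClusteringConfig(seed=1))
        table = classify_categories(G, sol)
        t = table.set_index(["variable", "level"]).cluster
        assert t[("a", "x")] == t[("b", "x")]
        assert t[("a", "y")] == t[("b", "y")]
        assert sorted(set(table.cluster)) == [1, 2]
        # sorted by cluster then labels
        assert list(table.cluster) == sorted(table.cluster)
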