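"""Unit, property, and cross-implementation tests for the clustering module."""

import numpy as np
import pytest

from mhcluster.clustering import (
    ClusteringError,
    KMeansConfig,
    assign_points,
    centroid_search_bounds,
    clustering_objective,
    decode_centroids,
    encode_centroids,
    euclidean_distance,
    exhaustive_optimal_partition,
    fwa_kmeans,
    kmeans,
    kmeanspp_init,
    sse_loss,
    update_centroids,
)
from mhcluster.fwa import FWAConfig

from conftest import make_blobs


class TestDistance:
    @pytest.mark.parametrize(
        "x, y, expected",
        [((0, 0), (3, 4), 5.0), ((1, 2), (1, 2), 0.0), ((1, 2, 3), (4, 6, 3), 5.0)],
    )
    def test_values(self, x, y, expected):
        assert euclidean_distance(x, y) == pytest.approx(expected)
        assert euclidean_distance(y, x) == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ClusteringError):
            euclidean_distance([1, 2], [1, 2, 3])


class TestAssignPoints:
    def test_nearest_by_inspection(self):
        labels = assign_points([[0.0], [10.0]], [[1.0], [9.0]])
        assert labels.tolist() == [0, 1]

    def test_tie_breaks_to_lowest_index(self):
        labels = assign_points([[5.0]], [[4.0], [6.0]])
        assert labels.tolist() == [0]

    def test_planted_points_recovered(self, rng):
        data, truth = make_blobs(rng, [[0, 0], [20, 20]], n_per=3, spread=0.1)
        labels = assign_points(data, [[0.0, 0.0], [20.0, 20.0]])
        assert labels.tolist() == truth.tolist()


class TestUpdateCentroids:
    def test_single_cluster_mean(self):
        centers = update_centroids([[0, 0], [2, 2]], [0, 0], 1)
        np.testing.assert_allclose(centers, [[1.0, 1.0]])

    def test_singleton_clusters_equal_samples(self):
        data = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        centers = update_centroids(data, [0, 1, 2], 3)
        np.testing.assert_allclose(centers, data)

    def test_empty_cluster_reseeded_with_farthest_sample(self):
        data = np.array([[0.0, 0.0], [1.0, 1.0], [9.0, 9.0]])
        centers = update_centroids(data, [0, 0, 0], 2)
        np.testing.assert_allclose(centers[1], [9.0, 9.0])
        np.testing.assert_allclose(centers[0], [0.5, 0.5])

    def test_more_clusters_than_samples_rejected(self):
        with pytest.raises(ClusteringError):
            update_centroids([[0.0]], [0], 2)


class TestSseLoss:
    def test_zero_when_samples_sit_on_centroids(self):
        data = np.array([[1.0, 1.0], [5.0, 5.0]])
        assert sse_loss(data, data, [0, 1]) == 0.0

    def test_hand_value(self):
        assert sse_loss([[0.0], [2.0]], [[1.0]], [0, 0]) == pytest.approx(2.0)

    def test_nearest_assignment_is_loss_optimal(self, rng):
        data = rng.uniform(0, 10, size=(12, 3))
        centers = rng.uniform(0, 10, size=(3, 3))
        best = sse_loss(data, centers, assign_points(data, centers))
        for _ in range(20):
            other = rng.integers(0, 3, size=12)
            assert best <= sse_loss(data, centers, other) + 1e-12


class TestKMeans:
    def test_fixed_point_converges_fast(self):
        data = np.array([[0.0], [0.2], [10.0], [10.2]])
        result = kmeans(data, KMeansConfig(K=2), [[0.1], [10.1]])
        assert result.converged
        assert result.iterations_run <= 2
        assert result.labels.tolist() == [0, 0, 1, 1]

    def test_two_separated_blobs_exact_solution(self):
        data = np.array([[0.0], [0.1], [10.0], [10.1]])
        result = kmeans(data, KMeansConfig(K=2), [[2.0], [8.0]])
        np.testing.assert_allclose(sorted(result.centroids.ravel()), [0.05, 10.05])
        assert result.loss == pytest.approx(0.01)

    def test_loss_non_increasing_and_consistent(self, rng):
        for _ in range(10):
            data = rng.uniform(0, 10, size=(30, 4))
            init = data[rng.choice(30, size=3, replace=False)]
            result = kmeans(data, KMeansConfig(K=3), init)
            h = result.loss_history
            assert all(a >= b - 1e-9 for a, b in zip(h, h[1:]))
            recomputed = sse_loss(data, result.centroids, result.labels)
            assert result.loss == pytest.approx(recomputed, abs=1e-12)

    def test_label_permutation_symmetry(self, rng):
        data = rng.uniform(0, 10, size=(40, 2))
        init = data[:3]
        r1 = kmeans(data, KMeansConfig(K=3), init)
        r2 = kmeans(data, KMeansConfig(K=3), init[::-1])
        assert r1.loss == pytest.approx(r2.loss, abs=1e-9)
        # permuting initial centroid order only renames the labels
        assert len(set(zip(r1.labels.tolist(), r2.labels.tolist()))) <= 3

    def test_matches_reference_implementation(self, rng):
        """Converged loss agrees with an independent K-means (scikit-learn)
        run from the identical initial centroids."""
        sklearn_cluster = pytest.importorskip("sklearn.cluster")
        for seed in range(10):
            local = np.random.default_rng(seed)
            data = local.uniform(0, 10, size=(60, 5))
            init = data[local.choice(60, size=4, replace=False)]
            ours = kmeans(data, KMeansConfig(K=4, loss_tolerance=0.0, max_iterations=300), init)
            ref = sklearn_cluster.KMeans(
                n_clusters=4, init=init, n_init=1, max_iter=300, tol=1e-12
            ).fit(data)
            assert ours.loss == pytest.approx(ref.inertia_, abs=1e-8)

    def test_non_finite_data_rejected(self):
        with pytest.raises(ClusteringError):
            kmeans([[np.nan]], KMeansConfig(K=1), [[0.0]])


class TestKMeansPP:
    def test_k1_center_is_a_data_row(self, rng):
        data = rng.uniform(0, 10, size=(8, 2))
        center = kmeanspp_init(data, 1, rng)
        assert any(np.allclose(center[0], row) for row in data)

    def test_k_equals_n_is_permutation(self, rng):
        data = np.arange(10, dtype=float).reshape(5, 2)
        centers = kmeanspp_init(data, 5, rng)
        assert {tuple(r) for r in centers} == {tuple(r) for r in data}

    def test_second_center_lands_in_opposite_blob(self):
        data = np.vstack([np.zeros((10, 2)), np.full((10, 2), 50.0)])
        data += np.random.default_rng(0).normal(0, 0.1, data.shape)
        opposite = 0
        for seed in range(200):
            centers = kmeanspp_init(data, 2, np.random.default_rng(seed))
            blob = [int(c[0] > 25) for c in centers]
            opposite += blob[0] != blob[1]
        assert opposite >= 195  # D^2 weighting makes same-blob picks vanishingly rare


class TestEncoding:
    def test_decode_reshapes_row_major(self):
        centers = decode_centroids([1, 2, 3, 4], 2, 2)
        np.testing.assert_array_equal(centers, [[1, 2], [3, 4]])

    def test_round_trip(self, rng):
        C = rng.uniform(0, 10, size=(3, 4))
        np.testing.assert_array_equal(decode_centroids(encode_centroids(C), 3, 4), C)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ClusteringError):
            decode_centroids([1, 2, 3], 2, 2)


class TestClusteringObjective:
    def test_stacked_centers_value(self):
        objective = clustering_objective([[0.0], [4.0]], 2)
        assert objective(np.array([0.0, 0.0])) == pytest.approx(16.0)

    def test_optimal_position_matches_oracle(self):
        data = np.array([[0.0, 0.0], [0.5, 0.0], [5.0, 5.0], [5.5, 5.0]])
        labels, best = exhaustive_optimal_partition(data, 2)
        means = np.vstack([data[labels == k].mean(axis=0) for k in range(2)])
        objective = clustering_objective(data, 2)
        assert objective(encode_centroids(means)) == pytest.approx(best, abs=1e-12)

    def test_invariant_to_center_block_permutation(self, rng):
        data = rng.uniform(0, 10, size=(10, 2))
        objective = clustering_objective(data, 3)
        pos = rng.uniform(0, 10, size=6)
        permuted = np.concatenate([pos[2:4], pos[0:2], pos[4:6]])
        assert objective(pos) == pytest.approx(objective(permuted))

    def test_search_bounds_cover_data_box(self, rng):
        data = rng.uniform(-3, 7, size=(20, 2))
        bounds = centroid_search_bounds(data, 4)
        assert bounds.shape == (8, 2)
        np.testing.assert_allclose(bounds[:2, 0], data.min(axis=0))
        np.testing.assert_allclose(bounds[:2, 1], data.max(axis=0))


class TestExhaustiveOracle:
    def test_separable_pair(self):
        labels, loss = exhaustive_optimal_partition([[0.0], [10.0]], 2)
        assert loss == 0.0
        assert labels[0] != labels[1]

    def test_three_points_hand_scored(self):
        labels, loss = exhaustive_optimal_partition([[0.0], [1.0], [10.0]], 2)
        assert loss == pytest.approx(0.5)
        assert labels[0] == labels[1] != labels[2]

    def test_k1_is_total_sum_of_squares(self, rng):
        data = rng.uniform(0, 10, size=(6, 2))
        _, loss = exhaustive_optimal_partition(data, 1)
        assert loss == pytest.approx(float(np.sum((data - data.mean(0)) ** 2)))

    def test_oversized_instance_refused(self):
        with pytest.raises(ClusteringError, match="too large"):
            exhaustive_optimal_partition(np.zeros((25, 1)), 10)


class TestFwaKmeans:
    FAST = FWAConfig(max_iterations=25)

    def test_recovers_planted_four_blob_partition(self, rng):
        data, truth = make_blobs(
            rng, [[0, 0], [10, 0], [0, 10], [10, 10]], n_per=8, spread=0.3
        )
        result = fwa_kmeans(data, 4, fwa_config=FWAConfig(max_iterations=50, seed=2))
        planted_centers = np.vstack([data[truth == k].mean(0) for k in range(4)])
        planted_loss = sse_loss(data, planted_centers, truth)
        assert result.loss == pytest.approx(planted_loss, abs=1e-9)

    def test_refinement_never_hurts(self, rng):
        from mhcluster.fwa import fwa_minimize
        from dataclasses import replace

        data = rng.uniform(0, 10, size=(30, 2))
        cfg = replace(self.FAST, seed=4, bounds=centroid_search_bounds(data, 3).tolist())
        fwa_result = fwa_minimize(clustering_objective(data, 3), cfg)
        hybrid = fwa_kmeans(data, 3, fwa_config=replace(self.FAST, seed=4))
        assert hybrid.loss <= fwa_result.best_fitness + 1e-9

    def test_n_equals_k_gives_zero_loss(self):
        data = np.array([[0.0, 0.0], [5.0, 5.0], [9.0, 1.0]])
        result = fwa_kmeans(data, 3, fwa_config=self.FAST)
        assert result.loss == pytest.approx(0.0, abs=1e-12)
        assert sorted(result.labels.tolist()) == [0, 1, 2]

    def test_deterministic_given_seeds(self, tiny_cohort):
        data = tiny_cohort.scores_matrix()[:40]
        cfg = FWAConfig(max_iterations=10, seed=5)
        r1 = fwa_kmeans(data, 4, fwa_config=cfg)
        r2 = fwa_kmeans(data, 4, fwa_config=cfg)
        np.testing.assert_array_equal(r1.labels, r2.labels)
        assert r1.loss == r2.loss
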