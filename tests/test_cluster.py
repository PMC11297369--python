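import itertools

import numpy as np
import pytest

from paintraj.cluster import (CLARA, ClusterSolution, KMedoids,
                              LongitudinalKMeans, best_of_runs, clara,
                              kmeans_longitudinal, kmedoids, wss)
from paintraj.features import pairwise_distances
from paintraj.sensitivity import match_clusters


def constant_points(levels):
    return np.array([[lvl] * 7 for lvl in levels], dtype=float)


def exhaustive_best_wss(X, k, metric="manhattan"):
    """Global minimum to-center WSS over all medoid subsets (brute force)."""
    distinct = np.unique(X, axis=0)
    best = np.inf
    for subset in itertools.combinations(range(len(distinct)), k):
        D = pairwise_distances(X, distinct[list(subset)], metric)
        best = min(best, D.min(axis=1).sum())
    return best


class TestKMedoids:
    def test_two_cluster_example_matches_enumeration(self):
        # constant-severity weeks at levels 1,1,2,5,5: the optimal pair of
        # medoids splits {1,1,2} from {5,5} with to-center WSS 7+0
        X = constant_points([1, 1, 2, 5, 5])
        sol = kmedoids(X, 2, seed=0)
        assert sol.wss == exhaustive_best_wss(X, 2) == 7.0
        groups = {frozenset(np.flatnonzero(sol.assignments == c).tolist())
                  for c in range(2)}
        assert groups == {frozenset({0, 1, 2}), frozenset({3, 4})}
        medoid_levels = sorted(sol.centers[:, 0].tolist())
        assert medoid_levels == [1.0, 5.0]

    def test_k_equals_n_gives_zero_wss(self):
        X = constant_points([1, 2, 3, 4, 5])
        sol = kmedoids(X, 5, seed=1)
        assert sol.wss == 0.0
        assert len(set(sol.assignments.tolist())) == 5

    @pytest.mark.parametrize("seed", range(5))
    def test_k1_medoid_is_brute_force_one_median(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.integers(1, 6, size=(12, 7)).astype(float)
        sol = kmedoids(X, 1, seed=seed)
        D = pairwise_distances(X, X, "manhattan")
        assert sol.wss == pytest.approx(D.sum(axis=0).min())

    def test_objective_history_non_increasing(self):
        rng = np.random.default_rng(2)
        X = rng.integers(1, 6, size=(60, 7)).astype(float)
        est = KMedoids(n_clusters=3, random_state=0).fit(X)
        hist = est.objective_history_
        assert all(a >= b - 1e-9 for a, b in zip(hist, hist[1:]))
        assert est.converged_

    def test_medoids_are_observed_points(self):
        rng = np.random.default_rng(3)
        X = rng.integers(1, 6, size=(40, 7)).astype(float)
        sol = kmedoids(X, 4, seed=3)
        for c in sol.centers:
            assert any(np.array_equal(c, x) for x in X)

    def test_errors(self):
        X = constant_points([1, 1, 1])
        with pytest.raises(ValueError, match="distinct"):
            kmedoids(X, 2, seed=0)
        with pytest.raises(ValueError):
            kmedoids(np.empty((0, 7)), 1, seed=0)

    def test_permutation_invariance_up_to_relabeling(self):
        # planted 4-level blobs with one jittered day per week: the
        # restart protocol finds the same partition from any input order
        rng = np.random.default_rng(6)
        X = np.repeat([[1.0] * 7, [2.0] * 7, [4.0] * 7, [5.0] * 7], 20, axis=0)
        day = rng.integers(0, 7, len(X))
        X[np.arange(len(X)), day] += rng.choice([-1.0, 1.0], len(X))
        X = np.clip(X, 1, 5)
        sol = best_of_runs(X, 4, method="kmedoids", n_runs=20, base_seed=9)
        perm = rng.permutation(len(X))
        sol_p = best_of_runs(X[perm], 4, method="kmedoids", n_runs=20, base_seed=9)
        back = np.empty(len(X), dtype=int)
        back[perm] = np.arange(len(X))
        aligned = ClusterSolution(
            k=4, method="kmedoids", metric="manhattan", centers=sol_p.centers,
            assignments=sol_p.assignments[back], wss=sol_p.wss, wss_mode="to_center",
        )
        _, agreement = match_clusters(sol, aligned)
        assert agreement == 100.0


class TestCLARA:
    def test_degenerate_clara_equals_kmedoids(self):
        rng = np.random.default_rng(8)
        X = rng.integers(1, 6, size=(50, 7)).astype(float)
        a = clara(X, 3, sample_size=len(X), n_samples=1, seed=42)
        b = kmedoids(X, 3, seed=42)
        assert a.wss == b.wss
        np.testing.assert_array_equal(a.assignments, b.assignments)

    def test_recovers_planted_blobs_and_matches_exhaustive(self):
        rng = np.random.default_rng(9)
        X = constant_points(list(np.repeat([1, 2, 4, 5], 15)))
        X = X[rng.permutation(len(X))]
        sol = clara(X, 4, seed=0)
        assert sol.wss == exhaustive_best_wss(X, 4) == 0.0
        assert sorted(sol.centers[:, 0].tolist()) == [1.0, 2.0, 4.0, 5.0]

    def test_same_seed_identical_solutions(self):
        rng = np.random.default_rng(10)
        X = rng.integers(1, 6, size=(120, 7)).astype(float)
        a = clara(X, 4, seed=7)
        b = clara(X, 4, seed=7)
        np.testing.assert_array_equal(a.assignments, b.assignments)
        assert a.wss == b.wss

    def test_sample_size_below_k_rejected(self):
        X = constant_points([1, 2, 3, 4, 5])
        with pytest.raises(ValueError, match="sample_size"):
            clara(X, 3, sample_size=2, seed=0)


class TestLongitudinalKMeans:
    def test_constant_levels_exact_centers(self):
        X = constant_points([1, 1, 5, 5])
        sol = kmeans_longitudinal(X, 2, seed=0)
        assert sol.wss == 0.0
        assert sorted(c[0] for c in sol.centers) == [1.0, 5.0]

    def test_k1_center_is_coordinate_mean(self):
        rng = np.random.default_rng(11)
        X = rng.integers(1, 6, size=(30, 7)).astype(float)
        sol = kmeans_longitudinal(X, 1, seed=0)
        np.testing.assert_allclose(sol.centers[0], X.mean(axis=0))

    def test_means_may_be_fractional(self):
        X = constant_points([1, 2, 4, 5])
        sol = kmeans_longitudinal(X, 2, seed=0)
        assert sorted(c[0] for c in sol.centers) == [1.5, 4.5]


class TestBestOfRuns:
    def test_single_run_equals_seeded_run(self):
        rng = np.random.default_rng(12)
        X = rng.integers(1, 6, size=(40, 7)).astype(float)
        a = best_of_runs(X, 3, method="kmedoids", n_runs=1, base_seed=5)
        b = kmedoids(X, 3, seed=5)
        assert a.wss == b.wss
        np.testing.assert_array_equal(a.assignments, b.assignments)

    def test_returns_minimum_over_runs(self):
        rng = np.random.default_rng(13)
        X = rng.integers(1, 6, size=(60, 7)).astype(float)
        best = best_of_runs(X, 4, method="kmedoids", n_runs=10, base_seed=0)
        singles = [kmedoids(X, 4, seed=s).wss for s in range(10)]
        assert best.wss == pytest.approx(min(singles))
        assert best.wss <= min(singles) + 1e-12

    def test_warm_start_makes_wss_non_increasing_in_k(self):
        rng = np.random.default_rng(14)
        X = rng.integers(1, 6, size=(100, 7)).astype(float)
        prev = best_of_runs(X, 1, method="kmedoids", n_runs=3, base_seed=0)
        for k in range(2, 8):
            cur = best_of_runs(X, k, method="kmedoids", n_runs=3, base_seed=0,
                               warm_start=prev)
            assert cur.wss <= prev.wss + 1e-9
            prev = cur

    def test_warm_start_requires_k_minus_one(self):
        X = constant_points([1, 2, 3, 4, 5])
        prev = kmedoids(X, 2, seed=0)
        with pytest.raises(ValueError, match="k-1"):
            best_of_runs(X, 4, method="kmedoids", n_runs=1, base_seed=0,
                         warm_start=prev)


class TestWss:
    def test_identical_points_zero_in_every_mode(self):
        X = constant_points([3, 3, 3])
        sol = kmedoids(X, 1, seed=0)
        for mode in ("to_center", "to_center_squared", "pairwise"):
            assert wss(X, sol, mode) == 0.0

    def test_hand_sums_single_cluster(self):
        X = constant_points([1, 1, 2])
        sol = kmedoids(X, 1, seed=0)
        assert wss(X, sol, "to_center") == 7.0  # medoid is a level-1 week
        assert wss(X, sol, "to_center_squared") == 49.0
        assert wss(X, sol, "pairwise") == 14.0  # 0 + 7 + 7

    @pytest.mark.parametrize("seed", range(4))
    def test_pairwise_mode_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.integers(1, 6, size=(15, 7)).astype(float)
        sol = kmedoids(X, 3, seed=seed)
        total = 0.0
        for c in range(3):
            members = np.flatnonzero(sol.assignments == c)
            for i, j in itertools.combinations(members, 2):
                total += np.abs(X[i] - X[j]).sum()
        assert wss(X, sol, "pairwise") == pytest.approx(total)

    def test_unknown_mode_rejected(self):
        X = constant_points([1, 2])
        sol = kmedoids(X, 1, seed=0)
        with pytest.raises(ValueError, match="mode"):
            wss(X, sol, "median")
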