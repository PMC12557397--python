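"""Four similarity measures, the distance matrix and the similarity map."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pathsim import (ContactTrajectory, DistanceMatrix, TrajectoryEnsemble,
                     distance_matrix, dtw_dependent, mean_euclidean,
                     procrustes_distance, to_similarity, wasserstein_distance)
from .conftest import random_trajectory
from .oracles import (dtw_brute_force, procrustes_svd, wasserstein_cdf,
                      wasserstein_sorted)


def traj(values, **kw):
    return ContactTrajectory(np.asarray(values, dtype=float), **kw)


class TestMeanEuclidean:
    def test_identical_is_zero(self, rng):
        a = random_trajectory(rng, 6, 3)
        assert mean_euclidean(a, a) == 0.0

    def test_three_four_five(self):
        # K=2, M=2: frames (0,0)/(0,0) vs (3,4)/(0,0) -> mean{5, 0} = 2.5
        a = traj([[0, 0], [0, 0]])
        b = traj([[3, 4], [0, 0]])
        assert mean_euclidean(a, b) == pytest.approx(2.5)

    def test_single_distance_frame_pair(self):
        a = traj([[0, 0], [0, 0]])
        b = traj([[3, 4], [3, 4]])
        assert mean_euclidean(a, b) == pytest.approx(5.0)

    def test_unequal_lengths_rejected(self, rng):
        with pytest.raises(ValueError, match="equal-length"):
            mean_euclidean(random_trajectory(rng, 5, 2), random_trajectory(rng, 6, 2))


class TestDTW:
    def test_identical_is_zero(self, rng):
        a = random_trajectory(rng, 7, 2)
        assert dtw_dependent(a, a) == 0.0

    def test_monotone_duplication_is_zero(self):
        a = traj([[1.0], [2.0]])
        b = traj([[1.0], [1.0], [2.0], [2.0]])
        assert dtw_dependent(a, b) == 0.0

    def test_small_grid_matches_path_enumeration(self):
        a = traj([[0.0], [0.0], [0.0]])
        b = traj([[0.0], [0.0], [1.0]])
        assert dtw_dependent(a, b) == pytest.approx(
            dtw_brute_force(a.values, b.values), abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_pairs_match_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k, kp, m = rng.integers(2, 9), rng.integers(2, 9), rng.integers(1, 4)
        a, b = random_trajectory(rng, k, m), random_trajectory(rng, kp, m)
        assert dtw_dependent(a, b) == pytest.approx(
            dtw_brute_force(a.values, b.values), abs=1e-10)

    def test_bounded_by_aligned_cost(self, rng):
        a, b = random_trajectory(rng, 12, 3), random_trajectory(rng, 12, 3)
        aligned = np.sqrt((np.linalg.norm(a.values - b.values, axis=1) ** 2).sum())
        assert dtw_dependent(a, b) <= aligned + 1e-12

    def test_squared_option(self, rng):
        a, b = random_trajectory(rng, 5, 2), random_trajectory(rng, 6, 2)
        assert dtw_dependent(a, b, squared=True) == pytest.approx(
            dtw_dependent(a, b) ** 2)

    def test_feature_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            dtw_dependent(random_trajectory(rng, 5, 2), random_trajectory(rng, 5, 3))


class TestProcrustes:
    def test_similarity_transform_is_zero(self, rng):
        a = random_trajectory(rng, 8, 2)
        theta = 1.1
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        b = traj(2.5 * a.values @ rot + np.array([3.0, -1.0]))
        assert procrustes_distance(a, b, stride=1) == pytest.approx(0.0, abs=1e-12)

    def test_sheared_square_matches_svd_oracle(self):
        square = traj([[0, 0], [1, 0], [1, 1], [0, 1]])
        shear = traj([[0, 0], [1, 0], [1.5, 1], [0.5, 1]])
        assert procrustes_distance(square, shear, stride=1) == pytest.approx(
            procrustes_svd(square.values, shear.values), abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_pairs_match_svd_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k, m = rng.integers(4, 20), rng.integers(1, 5)
        a, b = random_trajectory(rng, k, m), random_trajectory(rng, k, m)
        assert procrustes_distance(a, b, stride=1) == pytest.approx(
            procrustes_svd(a.values, b.values), abs=1e-10)

    def test_stride_downsamples(self, rng):
        a, b = random_trajectory(rng, 20, 2), random_trajectory(rng, 20, 2)
        assert procrustes_distance(a, b, stride=5) == pytest.approx(
            procrustes_svd(a.values[::5], b.values[::5]), abs=1e-10)

    def test_constant_trajectory_rejected(self, rng):
        a = traj(np.ones((6, 2)))
        with pytest.raises(ValueError, match="degenerate"):
            procrustes_distance(a, random_trajectory(rng, 6, 2), stride=1)


class TestWasserstein:
    def test_identical_is_zero(self, rng):
        a = random_trajectory(rng, 9, 2)
        assert wasserstein_distance(a, a) == 0.0

    def test_unit_translation_of_point_mass(self):
        assert wasserstein_distance(traj([[0.0], [0.0]]),
                                    traj([[1.0], [1.0]])) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_equal_length_sorted_sample_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k, m = rng.integers(2, 30), rng.integers(1, 4)
        a, b = random_trajectory(rng, k, m), random_trajectory(rng, k, m)
        expected = sum(wasserstein_sorted(a.values[:, j], b.values[:, j])
                       for j in range(m))
        assert wasserstein_distance(a, b) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_unequal_lengths_cdf_integration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = random_trajectory(rng, int(rng.integers(2, 20)), 2)
        b = random_trajectory(rng, int(rng.integers(2, 20)), 2)
        expected = sum(wasserstein_cdf(a.values[:, j], b.values[:, j])
                       for j in range(2))
        assert wasserstein_distance(a, b) == pytest.approx(expected, abs=1e-12)

    @given(st.integers(0, 1000))
    def test_time_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a, b = random_trajectory(rng, 10, 2), random_trajectory(rng, 12, 2)
        shuffled = traj(rng.permutation(a.values))
        assert wasserstein_distance(a, b) == pytest.approx(
            wasserstein_distance(shuffled, b), abs=1e-12)

    def test_triangle_inequality(self, rng):
        for _ in range(50):
            a, b, c = (random_trajectory(rng, 8, 2) for _ in range(3))
            assert wasserstein_distance(a, c) <= (
                wasserstein_distance(a, b) + wasserstein_distance(b, c) + 1e-12)


class TestDistanceMatrix:
    def test_n2_equals_pairwise_call(self, rng):
        a, b = random_trajectory(rng, 6, 2, "a"), random_trajectory(rng, 6, 2, "b")
        ens = TrajectoryEnsemble([a, b])
        dm = distance_matrix(ens, "euclidean")
        assert dm.values[0, 1] == mean_euclidean(a, b)

    def test_identical_trajectories_zero_matrix(self, rng):
        a = random_trajectory(rng, 6, 2)
        copies = [traj(a.values.copy(), contact_labels=list(a.contact_labels))
                  for _ in range(2)]
        ens = TrajectoryEnsemble([a, *copies])
        dm = distance_matrix(ens, "wasserstein")
        assert np.all(dm.values == 0.0)
        with pytest.raises(ValueError, match="no contrast"):
            to_similarity(dm)

    @pytest.mark.parametrize("measure", ["euclidean", "dtw", "procrustes", "wasserstein"])
    def test_symmetry_and_zero_diagonal(self, rng, measure):
        ens = TrajectoryEnsemble([random_trajectory(rng, 10, 3, f"t{i}")
                                  for i in range(4)])
        kwargs = {"stride": 2} if measure == "procrustes" else {}
        dm = distance_matrix(ens, measure, **kwargs)
        np.testing.assert_allclose(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0.0)

    def test_failing_pair_named(self, rng):
        ens = TrajectoryEnsemble([random_trajectory(rng, 5, 2, "left"),
                                  random_trajectory(rng, 6, 2, "right")])
        with pytest.raises(ValueError, match=r"\(left, right\)"):
            distance_matrix(ens, "euclidean")

    def test_unknown_measure_rejected(self, small_ensemble):
        with pytest.raises(ValueError, match="unknown measure"):
            distance_matrix(small_ensemble, "hausdorff")


class TestToSimilarity:
    def test_affine_map_values(self):
        d = np.array([[0, 0, 2], [0, 0, 4], [2, 4, 0]], dtype=float)
        s = to_similarity(DistanceMatrix(d, measure="euclidean"))
        assert s.values[0, 1] == pytest.approx(1.0)
        assert s.values[0, 2] == pytest.approx(0.5)
        assert s.values[1, 2] == pytest.approx(0.0)
        np.testing.assert_allclose(np.diag(s.values), 1.0)

    def test_rank_order_reversed(self, rng):
        ens = TrajectoryEnsemble([random_trajectory(rng, 8, 2, f"t{i}")
                                  for i in range(5)])
        dm = distance_matrix(ens, "euclidean")
        s = to_similarity(dm)
        iu = np.triu_indices(5, 1)
        assert np.all(np.argsort(dm.values[iu]) == np.argsort(-s.values[iu]))
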