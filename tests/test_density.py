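import numpy as np
import pytest

from gald.density import (
    LSD_EPS,
    euclidean_distance,
    k_distance,
    lsd,
    lsd_all,
    lsd_synthetic,
    neighborhood,
)


def brute_kdist(x, fd, k):
    return sorted(np.linalg.norm(fd - x, axis=1))[k - 1]


def brute_neighbor_ids(x, fd, k):
    d = np.linalg.norm(fd - x, axis=1)
    return set(np.flatnonzero(d <= brute_kdist(x, fd, k)))


def brute_lsd(x, fd, k):
    d = np.linalg.norm(fd - x, axis=1)
    return 1.0 / (d[d <= brute_kdist(x, fd, k)].sum() + LSD_EPS)


class TestEuclidean:
    def test_three_four_five(self):
        assert euclidean_distance([0, 0], [3, 4]) == 5.0

    def test_identity(self, rng):
        a = rng.normal(size=4)
        assert euclidean_distance(a, a) == 0.0

    def test_matches_termwise_sum(self, rng):
        a, b = rng.normal(size=5), rng.normal(size=5)
        oracle = np.sqrt(sum((ai - bi) ** 2 for ai, bi in zip(a, b)))
        assert euclidean_distance(a, b) == pytest.approx(oracle, rel=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            euclidean_distance([1, 2], [1, 2, 3])


class TestKDistance:
    def test_collinear(self):
        fd = np.array([[1.0, 0], [2, 0], [3, 0]])
        assert k_distance([0, 0], fd, 2) == 2.0

    def test_zero_when_on_synthetic_point(self):
        fd = np.array([[1.0, 1.0], [2, 2]])
        assert k_distance([1, 1], fd, 1) == 0.0

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            k_distance([0.0], np.zeros((3, 1)), 4)


class TestNeighborhood:
    def test_collinear(self):
        fd = np.array([[1.0, 0], [2, 0], [3, 0]])
        nb = neighborhood([0, 0], fd, 2)
        assert set(nb.neighbor_ids) == {0, 1}
        assert nb.k_distance == 2.0
        assert np.all(np.diff(nb.distances) >= 0)

    def test_ties_at_k_distance_all_included(self):
        fd = np.array([[1.0, 0], [0, 1], [2, 0]])
        nb = neighborhood([0, 0], fd, 1)
        assert set(nb.neighbor_ids) == {0, 1}
        assert len(nb.neighbor_ids) == 2  # the defining inequality is non-strict


class TestLsd:
    def test_two_unit_distances(self):
        fd = np.array([[1.0, 0], [0, 1]])
        assert lsd([0, 0], fd, 2) == pytest.approx(0.5)

    def test_distances_two_three(self):
        fd = np.array([[2.0, 0], [0, 3]])
        assert lsd([0, 0], fd, 2) == pytest.approx(0.2)

    def test_coincident_points_give_large_finite_density(self):
        fd = np.zeros((3, 2))
        val = lsd([0, 0], fd, 3)
        assert np.isfinite(val) and val == pytest.approx(1.0 / LSD_EPS)


class TestLsdAll:
    def test_single_row_reduces_to_scalar(self, rng):
        fd = rng.uniform(size=(20, 3))
        x = rng.uniform(size=3)
        np.testing.assert_allclose(lsd_all(x[None, :], fd, 4), [lsd(x, fd, 4)])

    def test_row_permutation_equivariance(self, rng):
        X = rng.uniform(size=(30, 2))
        fd = rng.uniform(size=(50, 2))
        perm = rng.permutation(30)
        np.testing.assert_allclose(lsd_all(X, fd, 5)[perm], lsd_all(X[perm], fd, 5))


class TestLsdSynthetic:
    def test_three_collinear_points(self):
        fd = np.array([[0.0], [1.0], [3.0]])
        # nearest non-self neighbors: 1, 1, 2 -> densities 1, 1, 0.5
        np.testing.assert_allclose(lsd_synthetic(fd, 1), [1.0, 1.0, 0.5])

    def test_identical_rows_all_equal(self):
        fd = np.zeros((5, 2))
        vals = lsd_synthetic(fd, 2)
        assert np.all(vals == vals[0])

    def test_requires_k_plus_one_rows(self):
        with pytest.raises(ValueError):
            lsd_synthetic(np.zeros((3, 1)), 3)

    def test_matches_leave_one_out_oracle(self, rng):
        fd = rng.uniform(size=(40, 3))
        k = 5
        vals = lsd_synthetic(fd, k)
        for i in range(40):
            rest = np.delete(fd, i, axis=0)
            assert vals[i] == pytest.approx(brute_lsd(fd[i], rest, k), rel=1e-12)


class TestOracleEquivalence:
    def test_many_random_instances(self):
        """k-distance, tie-inclusive neighborhood and LSD match brute force on
        50 random instances (s <= 100, d <= 10)."""
        rng = np.random.default_rng(2024)
        for trial in range(50):
            s = int(rng.integers(10, 101))
            d = int(rng.integers(1, 11))
            k = int(rng.integers(1, min(s, 15)))
            fd = rng.uniform(size=(s, d))
            x = rng.uniform(size=d)
            assert k_distance(x, fd, k) == pytest.approx(brute_kdist(x, fd, k), abs=1e-9)
            assert set(neighborhood(x, fd, k).neighbor_ids) == brute_neighbor_ids(x, fd, k)
            assert lsd(x, fd, k) == pytest.approx(brute_lsd(x, fd, k), rel=1e-9)
            X = rng.uniform(size=(5, d))
            np.testing.assert_allclose(
                lsd_all(X, fd, k), [brute_lsd(xi, fd, k) for xi in X], rtol=1e-9
            )


class TestGeometricInvariance:
    @staticmethod
    def _rigid(rng, d):
        A = rng.normal(size=(d, d))
        Q, _ = np.linalg.qr(A)
        t = rng.normal(size=d)
        return Q, t

    def test_rigid_transform_leaves_everything_unchanged(self, rng):
        d = 4
        X = rng.uniform(size=(20, d))
        fd = rng.uniform(size=(60, d))
        Q, t = self._rigid(rng, d)
        Xr, fdr = X @ Q + t, fd @ Q + t
        k = 7
        for i in range(5):
            assert k_distance(X[i], fd, k) == pytest.approx(k_distance(Xr[i], fdr, k), abs=1e-9)
            assert set(neighborhood(X[i], fd, k).neighbor_ids) == set(
                neighborhood(Xr[i], fdr, k).neighbor_ids
            )
        np.testing.assert_allclose(lsd_all(X, fd, k), lsd_all(Xr, fdr, k), rtol=1e-9)
        np.testing.assert_allclose(lsd_synthetic(fd, k), lsd_synthetic(fdr, k), rtol=1e-9)

    def test_scale_covariance(self, rng):
        X = rng.uniform(size=(10, 3))
        fd = rng.uniform(size=(40, 3))
        c = 3.7
        np.testing.assert_allclose(lsd_all(X * c, fd * c, 5), lsd_all(X, fd, 5) / c, rtol=1e-9)

    def test_lsd_decreases_when_neighbors_move_away(self, rng):
        """With the neighbor set fixed, inflating distances strictly lowers LSD."""
        x = np.zeros(2)
        fd_near = rng.uniform(0.5, 1.0, size=(10, 2))
        fd_far = fd_near * 1.5  # same set, larger distances from the origin
        assert lsd(x, fd_far, 10) < lsd(x, fd_near, 10)
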