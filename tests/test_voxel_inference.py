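"""Voxelwise regression t-maps and cluster-extent permutation inference."""

import numpy as np
import pytest
from scipy import stats as sps

from _oracles import bfs_label
from atrophymap.errors import ConfigurationError, DataError, StatisticsError, UsageError
from atrophymap.voxel_inference import (
    T_CAP,
    ClusterSet,
    TMap,
    label_clusters,
    permutation_null,
    significant_clusters,
    voxelwise_slope_t,
)


def _maps_from_matrix(data, shape):
    """Per-subject 3-D arrays from an (n_subjects, n_voxels) matrix."""
    return [row.reshape(shape) for row in data]


class TestSlopeT:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("n", [5, 12, 40])
    def test_matches_correlation_closed_form(self, seed, n):
        """t at each voxel equals r sqrt(n-2)/sqrt(1-r^2)."""
        rng = np.random.default_rng(seed)
        shape = (4, 4, 4)
        data = rng.normal(size=(n, 64))
        x = rng.normal(size=n)
        tmap = voxelwise_slope_t(_maps_from_matrix(data, shape), x, np.ones(shape, bool))
        r = np.array([np.corrcoef(x, data[:, v])[0, 1] for v in range(64)])
        expected = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
        np.testing.assert_allclose(tmap.values.ravel(), expected, atol=1e-10)

    def test_null_t_values_follow_student_t(self):
        """Independent data: voxelwise t ~ t(n-2); KS non-rejecting at 1%."""
        rng = np.random.default_rng(7)
        n, shape = 20, (12, 12, 12)
        data = rng.normal(size=(n, 12**3))
        x = rng.normal(size=n)
        tmap = voxelwise_slope_t(_maps_from_matrix(data, shape), x, np.ones(shape, bool))
        _, p = sps.kstest(tmap.values.ravel(), sps.t(df=n - 2).cdf)
        assert p > 0.01

    def test_intercept_absorbs_per_map_constant_shifts(self, rng):
        n, shape = 10, (5, 5, 5)
        data = rng.normal(size=(n, 125))
        x = rng.normal(size=n)
        mask = np.ones(shape, bool)
        t0 = voxelwise_slope_t(_maps_from_matrix(data, shape), x, mask)
        shifted = data + 3.25
        t1 = voxelwise_slope_t(_maps_from_matrix(shifted, shape), x, mask)
        np.testing.assert_allclose(t1.values, t0.values, atol=1e-10)

    def test_perfect_fit_is_capped_and_flagged(self):
        x = np.array([0.1, 0.4, 0.7, 1.0, 1.3])
        shape = (2, 2, 2)
        data = np.outer(x, np.ones(8)) * 2.0 + 5.0  # exactly a*x + b at every voxel
        tmap = voxelwise_slope_t(_maps_from_matrix(data, shape), x, np.ones(shape, bool))
        assert np.all(tmap.values == T_CAP)
        assert tmap.capped.all()

    def test_degenerate_inputs_raise(self, rng):
        shape = (3, 3, 3)
        maps = _maps_from_matrix(rng.normal(size=(5, 27)), shape)
        with pytest.raises(StatisticsError):
            voxelwise_slope_t(maps, np.ones(5), np.ones(shape, bool))
        with pytest.raises(StatisticsError):
            voxelwise_slope_t(maps[:3], rng.normal(size=3), np.ones(shape, bool))
        with pytest.raises(DataError):
            voxelwise_slope_t(maps, rng.normal(size=5), np.ones((4, 4, 4), bool))


class TestClusterLabeling:
    def _tmap(self, values):
        values = np.asarray(values, dtype=float)
        return TMap(values=values, n_subjects=10, mask=np.ones(values.shape, bool))

    def test_no_suprathreshold_voxels_no_clusters(self):
        cs = label_clusters(self._tmap(np.zeros((5, 5, 5))), 3.5)
        assert cs.n_clusters == 0 and cs.max_size == 0

    def test_single_isolated_voxel(self):
        v = np.zeros((5, 5, 5))
        v[2, 2, 2] = 4.0
        cs = label_clusters(self._tmap(v), 3.5, connectivity=6)
        assert cs.n_clusters == 1 and list(cs.sizes) == [1]

    def test_corner_touching_blobs_split_by_connectivity(self):
        """Two blobs sharing only a corner: one cluster under 26-connectivity,
        two under 6-connectivity."""
        v = np.zeros((8, 8, 8))
        v[1:3, 1:3, 1:3] = 5.0
        v[3:5, 3:5, 3:5] = 5.0
        assert label_clusters(self._tmap(v), 3.5, connectivity=26).n_clusters == 1
        assert label_clusters(self._tmap(v), 3.5, connectivity=6).n_clusters == 2

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_bfs_oracle_on_random_grids(self, connectivity, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(5, 13, size=3))
        v = rng.normal(size=shape)
        cs = label_clusters(self._tmap(v), 0.8, connectivity=connectivity)
        oracle_labels, oracle_sizes = bfs_label(v > 0.8, connectivity)
        assert cs.n_clusters == len(oracle_sizes)
        assert sorted(cs.sizes) == sorted(oracle_sizes)
        # identical partitions: labels agree up to renaming
        for lab in range(1, cs.n_clusters + 1):
            voxels = cs.label_map == lab
            assert len(np.unique(oracle_labels[voxels])) == 1

    def test_voxel_volume_propagates_to_cm3(self):
        v = np.zeros((4, 4, 4))
        v[:2, 0, 0] = 9.0
        cs = label_clusters(self._tmap(v), 3.5, voxel_volume_cm3=0.008)
        np.testing.assert_allclose(cs.volumes_cm3, [0.016])


class TestPermutationNull:
    def _setup(self, seed=0, n=16, shape=(8, 8, 8)):
        rng = np.random.default_rng(seed)
        data = rng.normal(size=(n, int(np.prod(shape))))
        x = rng.normal(size=n)
        return _maps_from_matrix(data, shape), x, np.ones(shape, bool)

    def test_seeded_runs_are_identical(self):
        maps, x, mask = self._setup()
        a = permutation_null(maps, x, mask, n_perm=120, seed=9)
        b = permutation_null(maps, x, mask, n_perm=120, seed=9)
        np.testing.assert_array_equal(a.max_cluster_sizes, b.max_cluster_sizes)
        assert a.critical_size == b.critical_size

    def test_identical_maps_across_subjects_give_zero_max_sizes(self):
        shape = (6, 6, 6)
        template = np.random.default_rng(0).normal(size=shape)
        maps = [template.copy() for _ in range(8)]
        x = np.arange(8, dtype=float)
        null = permutation_null(maps, x, np.ones(shape, bool), n_perm=100, seed=0)
        assert np.all(null.max_cluster_sizes == 0)

    def test_too_few_permutations_rejected(self):
        maps, x, mask = self._setup()
        with pytest.raises(ConfigurationError):
            permutation_null(maps, x, mask, n_perm=50, seed=0)

    def test_critical_size_is_attained_order_statistic(self):
        maps, x, mask = self._setup(seed=3)
        null = permutation_null(maps, x, mask, t_threshold=2.0, n_perm=200, seed=3)
        assert null.critical_size in null.max_cluster_sizes


class TestSignificantClusters:
    def _observed(self, sizes, shape=(10, 10, 10), connectivity=26, t_threshold=3.5):
        """Build a ClusterSet with disjoint line clusters of given sizes."""
        label_map = np.zeros(shape, dtype=int)
        for i, s in enumerate(sizes, start=1):
            label_map[2 * (i - 1), :s, 0] = i
        return ClusterSet(
            label_map=label_map,
            sizes=np.array(sizes, dtype=int),
            volumes_cm3=np.array(sizes, dtype=float),
            t_threshold=t_threshold,
            connectivity=connectivity,
        )

    def _null(self, max_sizes, t_threshold=3.5, connectivity=26):
        from atrophymap.voxel_inference import PermutationNull

        max_sizes = np.asarray(max_sizes, dtype=int)
        order = np.sort(max_sizes)
        k = int(np.ceil(0.95 * len(order)))
        return PermutationNull(
            max_cluster_sizes=max_sizes,
            n_perm=len(max_sizes),
            seed=0,
            critical_size=int(order[k - 1]),
            t_threshold=t_threshold,
            connectivity=connectivity,
        )

    def test_no_cluster_beats_null_gives_empty_mask(self):
        sig = significant_clusters(self._observed([3, 2]), self._null([5] * 200))
        assert not sig.mask.any() and sig.cluster_labels == []

    def test_cluster_above_all_null_maxima_hits_p_floor(self):
        null = self._null(list(range(200)))
        sig = significant_clusters(self._observed([500]), null)
        assert sig.corrected_p == [pytest.approx(1 / 201)]
        assert sig.cluster_sizes == [500]

    def test_mismatched_settings_raise(self):
        with pytest.raises(UsageError):
            significant_clusters(
                self._observed([5], t_threshold=3.0), self._null([1] * 100)
            )

    def test_relabeling_clusters_changes_nothing(self):
        """Permuting cluster IDs leaves sizes and the significant mask intact."""
        obs = self._observed([8, 2, 6])
        null = self._null([4] * 100)
        sig = significant_clusters(obs, null)
        relabeled = ClusterSet(
            label_map=np.select(
                [obs.label_map == 1, obs.label_map == 2, obs.label_map == 3],
                [3, 1, 2],
            ),
            sizes=np.array([2, 6, 8]),
            volumes_cm3=np.array([2.0, 6.0, 8.0]),
            t_threshold=obs.t_threshold,
            connectivity=obs.connectivity,
        )
        sig2 = significant_clusters(relabeled, null)
        np.testing.assert_array_equal(sig.mask, sig2.mask)
        assert sorted(sig.cluster_sizes) == sorted(sig2.cluster_sizes)
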