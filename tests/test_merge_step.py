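import numpy as np
import pytest

from emfi import classify_subregions, heterogeneity_test, merge_nonclustered, subregion_density
from emfi.merge_step import Subregion, build_subregions, region_demand_density


class TestSubregionDensity:
    def test_unit_square_hand_area(self):
        coords = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        total, area, density = subregion_density(coords, np.full(4, 25.0))
        assert (total, area, density) == (100.0, 1.0, 100.0)

    def test_collinear_degenerate(self):
        total, area, density = subregion_density(np.array([[0.0, 0.0], [1.0, 1.0]]), np.ones(2))
        assert area == 0.0 and np.isnan(density)

    def test_density_scales_with_weights(self):
        coords = np.array([[0, 0], [2, 0], [2, 2], [0, 2]], dtype=float)
        w = np.array([1.0, 2.0, 3.0, 4.0])
        _, area1, d1 = subregion_density(coords, w)
        _, area2, d2 = subregion_density(coords, 2 * w)
        assert area1 == area2 and d2 == 2 * d1


class TestHeterogeneityTest:
    def test_one_point_per_cell_hand_values(self):
        # 2x2 grid, 4 points, one per cell: binomial(4, 1/4) expectation
        coords = np.array([[0.1, 0.1], [0.9, 0.1], [0.1, 0.9], [0.9, 0.9]])
        res = heterogeneity_test(coords, n_cells=4)
        assert res.n_cells == 4 and res.dof == 4
        assert np.allclose(
            res.expected, [1.265625, 1.6875, 0.84375, 0.1875, 0.015625], atol=1e-6
        )
        assert res.observed.tolist() == [0.0, 4.0, 0.0, 0.0, 0.0]
        assert res.chi2 == pytest.approx(5.4815, abs=1e-3)
        assert not res.reject  # homogeneous at alpha = 0.05

    def test_total_concentration_rejects(self):
        coords = np.vstack([np.tile([[3.0, 3.0]], (49, 1)), [[30.0, 30.0]]])
        res = heterogeneity_test(coords, n_cells=100)
        assert res.reject and res.chi2 > 1e3

    def test_observed_counts_sum_to_cells(self):
        rng = np.random.default_rng(1)
        for n_sub, n_cells in [(10, 16), (100, 100), (37, 25)]:
            res = heterogeneity_test(rng.uniform(size=(n_sub, 2)), n_cells=n_cells)
            assert res.observed.sum() == res.n_cells
            assert res.expected.sum() == pytest.approx(res.n_cells, abs=1e-6)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            heterogeneity_test(np.empty((0, 2)))

    def test_conservative_on_uniform_scatter(self):
        # dof = n_sub makes the test under-reject: rate stays below alpha
        rng = np.random.default_rng(6)
        rejections = sum(
            heterogeneity_test(rng.uniform(size=(100, 2)), n_cells=100).reject
            for _ in range(200)
        )
        assert rejections / 200 <= 0.05


def _clumpy_blob(rng, n=100):
    """A center-heavy blob with empty corners: clearly heterogeneous."""
    core = rng.normal(scale=1.0, size=(n - 4, 2))
    corners = np.array([[10, 10], [-10, 10], [10, -10], [-10, -10]], dtype=float)
    return np.vstack([core, corners])


class TestClassify:
    def test_equal_density_is_not_sparse(self):
        coords = np.array([[0, 0], [4, 0], [4, 4], [0, 4]], dtype=float)
        w = np.ones(4)
        subs = build_subregions(coords, w, np.zeros(4, dtype=int))
        classify_subregions(subs, coords, region_demand_density(coords, w))
        assert not subs[0].is_sparse  # strict < at the boundary

    def test_blob_in_sparse_field(self):
        rng = np.random.default_rng(3)
        blob = _clumpy_blob(rng)
        field = rng.uniform(-200, 200, size=(150, 2))
        coords = np.vstack([blob, field])
        w = np.concatenate([np.full(len(blob), 50.0), np.ones(len(field))])
        labels = np.concatenate([np.zeros(len(blob), dtype=int), np.ones(len(field), dtype=int)])
        subs = build_subregions(coords, w, labels)
        classify_subregions(subs, coords, region_demand_density(coords, w))
        assert subs[0].is_clustered
        assert not subs[1].is_clustered

    def test_single_member_is_sparse(self):
        coords = np.array([[0, 0], [50, 50], [50, 0], [0, 50], [100, 100]], dtype=float)
        w = np.ones(5)
        labels = np.array([0, 0, 0, 0, 1])
        subs = build_subregions(coords, w, labels)
        classify_subregions(subs, coords, region_demand_density(coords, w))
        assert subs[1].is_sparse


class TestMerge:
    @staticmethod
    def _manual_subregion(coords, w, members, sparse, homog):
        members = np.asarray(members, dtype=np.intp)
        total, area, density = subregion_density(coords[members], w[members])
        return Subregion(
            members=members,
            centroid=coords[members].mean(axis=0),
            total_demand=total,
            area=area,
            density=density,
            is_sparse=sparse,
            is_homogeneous=homog,
        )

    def test_all_clustered_is_noop(self):
        coords = np.array([[0, 0], [1, 0], [0, 1], [10, 10], [11, 10], [10, 11]], dtype=float)
        w = np.ones(6)
        subs = [
            self._manual_subregion(coords, w, [0, 1, 2], False, False),
            self._manual_subregion(coords, w, [3, 4, 5], False, False),
        ]
        merged = merge_nonclustered(subs, coords, w)
        assert len(merged) == 2

    def test_single_cluster_absorbs_everything(self):
        coords = np.array([[0, 0], [1, 0], [0, 1], [50, 50]], dtype=float)
        w = np.ones(4)
        subs = [
            self._manual_subregion(coords, w, [0, 1, 2], False, False),
            self._manual_subregion(coords, w, [3], True, True),
        ]
        merged = merge_nonclustered(subs, coords, w)
        assert len(merged) == 1
        assert sorted(merged[0].members.tolist()) == [0, 1, 2, 3]

    def test_split_by_nearest_centroid(self):
        coords = np.array(
            [[0, 0], [1, 1], [-1, 1], [100, 0], [101, 1], [99, 1], [30, 0], [70, 0]],
            dtype=float,
        )
        w = np.ones(8)
        subs = [
            self._manual_subregion(coords, w, [0, 1, 2], False, False),
            self._manual_subregion(coords, w, [3, 4, 5], False, False),
            self._manual_subregion(coords, w, [6, 7], True, True),
        ]
        merged = merge_nonclustered(subs, coords, w)
        assert 6 in merged[0].members and 7 in merged[1].members

    def test_fully_homogeneous_raises(self):
        coords = np.array([[0, 0], [1, 0], [0, 1]], dtype=float)
        w = np.ones(3)
        subs = [self._manual_subregion(coords, w, [0, 1, 2], True, True)]
        with pytest.raises(ValueError, match="homogeneous"):
            merge_nonclustered(subs, coords, w)

    def test_partition_and_demand_conservation(self):
        rng = np.random.default_rng(9)
        coords = np.vstack(
            [c + rng.normal(scale=1.5, size=(40, 2)) for c in ([0, 0], [60, 0], [0, 60])]
        )
        coords = np.vstack([coords, rng.uniform(-20, 80, size=(40, 2))])
        w = rng.uniform(1, 10, size=len(coords))
        labels = np.concatenate([np.repeat([0, 1, 2], 40), np.full(40, 3)])
        subs = build_subregions(coords, w, labels)
        classify_subregions(subs, coords, region_demand_density(coords, w))
        before = sum(s.total_demand for s in subs)
        merged = merge_nonclustered(subs, coords, w)
        all_members = np.concatenate([s.members for s in merged])
        assert sorted(all_members.tolist()) == list(range(len(coords)))
        assert sum(s.total_demand for s in merged) == pytest.approx(before, rel=1e-12)
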