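import numpy as np
import pandas as pd
import pytest

from cerebparc import (
    boundary_table,
    default_bin_edges,
    generate_geometry,
    global_dcbc,
    homogeneity,
    homogeneity_table,
    local_dcbc,
    negative_boundary_report,
    pairwise_bin_correlations,
    region_adjacency,
)
from cerebparc.bold import BoldSeries
from cerebparc.errors import (
    EmptyResultError,
    InvalidArgumentError,
    UndefinedResultError,
)
from cerebparc.evaluation import BoundaryTable
from cerebparc.parcellation import Parcellation


def _series(data, geom, sid="s0"):
    return BoldSeries(subject_id=sid, condition="synthetic", data=np.asarray(data, float),
                      geometry=geom)


def _parc(labels, geom):
    labels = np.asarray(labels, dtype=np.int64)
    return Parcellation(labels=labels, geometry=geom, K=int(labels.max()),
                        threshold=np.nan)


class TestHomogeneity:
    def test_rank_one_parcel_has_ratio_one(self, small_geometry):
        rng = np.random.default_rng(0)
        tc = rng.standard_normal(50)
        data = np.tile(tc[:, None], (1, small_geometry.n_voxels))
        # scatter with random gains: still rank 1 after standardization
        data *= rng.uniform(0.5, 2.0, small_geometry.n_voxels)
        parc = _parc(np.ones(small_geometry.n_voxels), small_geometry)
        res = homogeneity(_series(data, small_geometry), parc)
        assert res.table["eigen_ratio"].iloc[0] == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_pair_has_ratio_half(self):
        geom = generate_geometry((1, 1, 2), 2.0)
        T = 40
        t = np.arange(T) * 2 * np.pi / T
        data = np.stack([np.sin(t), np.cos(t)], axis=1)  # orthogonal, equal var
        parc = _parc([1, 1], geom)
        res = homogeneity(_series(data, geom), parc)
        assert res.table["eigen_ratio"].iloc[0] == pytest.approx(0.5, abs=1e-10)

    def test_matches_dense_eigensolver(self, small_geometry):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((30, small_geometry.n_voxels))
        labels = np.zeros(small_geometry.n_voxels, dtype=int)
        labels[:10] = 1
        parc = _parc(labels, small_geometry)
        res = homogeneity(_series(data, small_geometry), parc)
        Z = data[:, :10]
        Z = (Z - Z.mean(0)) / Z.std(0)
        eig = np.linalg.eigvalsh(np.cov(Z, rowvar=False))
        assert res.table["eigen_ratio"].iloc[0] == pytest.approx(
            eig[-1] / eig.sum(), abs=1e-10
        )

    def test_ratio_bounds_hold(self, planted_dataset):
        series, truth = planted_dataset
        parc = _parc(truth.true_labels, series[0].geometry)
        res = homogeneity_table(series, parc)
        sizes = res.table["size"].to_numpy()
        T = series[0].n_timepoints
        lower = 1.0 / np.minimum(T, sizes)
        ratios = res.table["eigen_ratio"].to_numpy()
        assert np.all(ratios >= lower - 1e-12)
        assert np.all(ratios <= 1.0 + 1e-12)

    def test_empty_parcellation_rejected(self, small_geometry):
        data = np.random.default_rng(0).standard_normal((10, 125))
        parc = _parc(np.zeros(125), small_geometry)
        with pytest.raises(InvalidArgumentError):
            homogeneity(_series(data, small_geometry), parc)


def brute_force_bin_stats(data_list, coords, labels, edges):
    """Independent exhaustive-enumeration oracle for the DCBC bin table."""
    n_bins = len(edges) - 1
    V = len(labels)
    sums_w = np.zeros(n_bins)
    sums_b = np.zeros(n_bins)
    n_w = np.zeros(n_bins, dtype=int)
    n_b = np.zeros(n_bins, dtype=int)
    S = len(data_list)
    for Z in data_list:
        for i in range(V):
            for j in range(i + 1, V):
                if labels[i] == 0 or labels[j] == 0:
                    continue
                d = float(np.linalg.norm(coords[i] - coords[j]))
                b = None
                for bi in range(n_bins):
                    if edges[bi] < d <= edges[bi + 1]:
                        b = bi
                        break
                if b is None:
                    continue
                r = np.corrcoef(Z[:, i], Z[:, j])[0, 1]
                if labels[i] == labels[j]:
                    sums_w[b] += r
                else:
                    sums_b[b] += r
    for Z in data_list[:1]:
        for i in range(V):
            for j in range(i + 1, V):
                if labels[i] == 0 or labels[j] == 0:
                    continue
                d = float(np.linalg.norm(coords[i] - coords[j]))
                for bi in range(n_bins):
                    if edges[bi] < d <= edges[bi + 1]:
                        if labels[i] == labels[j]:
                            n_w[bi] += 1
                        else:
                            n_b[bi] += 1
    with np.errstate(invalid="ignore"):
        return (np.where(n_w > 0, sums_w / (n_w * S), np.nan),
                np.where(n_b > 0, sums_b / (n_b * S), np.nan), n_w, n_b)


class TestDcbc:
    def test_identical_timecourses_give_zero_dcbc(self):
        geom = generate_geometry((3, 3, 1), 3.0)
        tc = np.sin(np.arange(30))
        data = np.tile(tc[:, None], (1, 9))
        parc = _parc([1, 1, 1, 1, 2, 2, 2, 2, 2], geom)
        res = pairwise_bin_correlations([_series(data, geom)], parc)
        populated = res.weight > 0
        np.testing.assert_allclose(res.within_corr[populated], 1.0, atol=1e-10)
        np.testing.assert_allclose(res.between_corr[populated], 1.0, atol=1e-10)
        assert global_dcbc(res) == pytest.approx(0.0, abs=1e-10)

    def test_matches_exhaustive_enumeration_on_toy_grid(self):
        geom = generate_geometry((3, 1, 1), 4.0)
        data = np.array([[1.0, 2.0, 5.0],
                         [2.0, 1.0, 4.0],
                         [3.0, 5.0, 1.0],
                         [4.0, 4.0, 2.0]])
        parc = _parc([1, 1, 2], geom)
        series = [_series(data, geom)]
        edges = np.array([0.0, 4.5, 9.0])
        res = pairwise_bin_correlations(series, parc, geom, bin_edges=edges)
        from cerebparc.decomposition import standardize_series

        Z = [standardize_series(s).data for s in series]
        w, b, n_w, n_b = brute_force_bin_stats(Z, geom.coords, parc.labels, edges)
        np.testing.assert_allclose(res.within_corr, w, atol=1e-12, equal_nan=True)
        np.testing.assert_allclose(res.between_corr, b, atol=1e-12, equal_nan=True)
        np.testing.assert_array_equal(res.n_within_pairs, n_w)
        np.testing.assert_array_equal(res.n_between_pairs, n_b)

    def test_matches_oracle_on_random_grid_multi_subject(self):
        geom = generate_geometry((4, 3, 2), 3.0)
        rng = np.random.default_rng(3)
        series = [_series(rng.standard_normal((25, 24)), geom, f"s{i}")
                  for i in range(2)]
        labels = rng.integers(0, 3, 24)
        parc = _parc(labels, geom)
        edges = default_bin_edges()
        res = pairwise_bin_correlations(series, parc, geom, bin_edges=edges)
        from cerebparc.decomposition import standardize_series

        Z = [standardize_series(s).data for s in series]
        w, b, n_w, n_b = brute_force_bin_stats(Z, geom.coords, labels, edges)
        np.testing.assert_allclose(res.within_corr, w, atol=1e-10, equal_nan=True)
        np.testing.assert_allclose(res.between_corr, b, atol=1e-10, equal_nan=True)
        np.testing.assert_array_equal(res.n_within_pairs, n_w)
        np.testing.assert_array_equal(res.n_between_pairs, n_b)

    def test_permutation_invariance_of_bin_statistics(self):
        geom = generate_geometry((3, 3, 2), 2.0)
        rng = np.random.default_rng(4)
        data = rng.standard_normal((30, 18))
        labels = rng.integers(1, 4, 18)
        res1 = pairwise_bin_correlations([_series(data, geom)], _parc(labels, geom), geom)
        # permute voxel order consistently in data, coords and labels
        perm = rng.permutation(18)
        from cerebparc.geometry import VoxelGeometry

        geom2 = VoxelGeometry(voxel_ids=geom.voxel_ids[perm], coords=geom.coords[perm],
                              grid_shape=geom.grid_shape, spacing=geom.spacing)
        res2 = pairwise_bin_correlations([_series(data[:, perm], geom2)],
                                         _parc(labels[perm], geom2), geom2)
        np.testing.assert_allclose(res1.within_corr, res2.within_corr,
                                   atol=1e-12, equal_nan=True)
        np.testing.assert_allclose(res1.between_corr, res2.between_corr,
                                   atol=1e-12, equal_nan=True)

    def test_weights_sum_to_one_over_populated_bins(self, planted_dataset):
        series, truth = planted_dataset
        parc = _parc(truth.true_labels, series[0].geometry)
        res = pairwise_bin_correlations(series[:2], parc)
        assert res.weight.sum() == pytest.approx(1.0)
        missing = (res.n_within_pairs == 0) | (res.n_between_pairs == 0)
        assert np.all(res.weight[missing] == 0.0)

    def test_fisher_averaging_matches_manual_transform(self):
        geom = generate_geometry((3, 2, 1), 3.0)
        rng = np.random.default_rng(9)
        series = [_series(rng.standard_normal((30, 6)), geom, f"s{i}")
                  for i in range(3)]
        parc = _parc([1, 1, 1, 2, 2, 2], geom)
        plain = pairwise_bin_correlations(series, parc, geom)
        fish = pairwise_bin_correlations(series, parc, geom, fisher_average=True)
        # recompute one populated bin by hand
        from cerebparc.decomposition import standardize_series as stdz

        b = int(np.flatnonzero(fish.n_within_pairs > 0)[0])
        iu = np.triu_indices(6, 1)
        from scipy.spatial.distance import pdist

        d = pdist(geom.coords)
        bins = np.searchsorted(fish.bin_edges, d, side="left") - 1
        labels = parc.labels
        sel = (bins == b) & (labels[iu[0]] == labels[iu[1]])
        zs = []
        for s in series:
            Z = stdz(s).data
            R = (Z.T @ Z) / Z.shape[0]
            zs.append(np.arctanh(R[iu][sel]))
        expected = np.tanh(np.mean(np.concatenate(zs)))
        assert fish.within_corr[b] == pytest.approx(expected, abs=1e-12)
        assert fish.within_corr[b] != plain.within_corr[b]

    def test_single_bin_difference(self):
        res_edges = np.array([0.0, 10.0])
        from cerebparc.evaluation import DcbcResult

        d = DcbcResult(bin_edges=res_edges, within_corr=np.array([0.6]),
                       between_corr=np.array([0.2]), n_within_pairs=np.array([5]),
                       n_between_pairs=np.array([5]), weight=np.array([1.0]))
        assert global_dcbc(d) == pytest.approx(0.4)

    def test_no_eligible_bin_is_undefined(self):
        from cerebparc.evaluation import DcbcResult

        d = DcbcResult(bin_edges=np.array([0.0, 3.0]), within_corr=np.array([np.nan]),
                       between_corr=np.array([0.2]), n_within_pairs=np.array([0]),
                       n_between_pairs=np.array([5]), weight=np.array([0.0]))
        with pytest.raises(UndefinedResultError):
            global_dcbc(d)

    def test_all_label_zero_is_empty_result(self, small_geometry):
        data = np.random.default_rng(0).standard_normal((10, 125))
        parc = _parc(np.zeros(125), small_geometry)
        with pytest.raises(EmptyResultError):
            pairwise_bin_correlations([_series(data, small_geometry)], parc)


class TestAdjacency:
    def test_two_blocks_share_one_boundary(self):
        geom = generate_geometry((4, 1, 1), 2.0)
        parc = _parc([1, 1, 2, 2], geom)
        assert region_adjacency(parc, geom) == [(1, 2)]

    def test_checkerboard_has_single_boundary(self):
        geom = generate_geometry((4, 4, 1), 2.0)
        idx = geom.grid_indices()
        labels = 1 + (idx[:, 0] + idx[:, 1]) % 2
        parc = _parc(labels, geom)
        pairs = region_adjacency(parc, geom)
        assert pairs == [(1, 2)]

    def test_zero_slab_separates_regions(self):
        geom = generate_geometry((5, 1, 1), 2.0)
        parc = _parc([1, 1, 0, 2, 2], geom)
        assert region_adjacency(parc, geom) == []


class TestLocalDcbc:
    def test_two_region_parcellation_local_equals_global(self):
        geom = generate_geometry((4, 2, 1), 3.0)
        rng = np.random.default_rng(5)
        series = [_series(rng.standard_normal((40, 8)), geom)]
        parc = _parc([1, 1, 1, 1, 2, 2, 2, 2], geom)
        g = global_dcbc(pairwise_bin_correlations(series, parc, geom))
        l = local_dcbc(series, parc, geom, 1, 2)
        assert l == pytest.approx(g, abs=1e-12)

    def test_planted_boundary_is_positive(self):
        geom = generate_geometry((4, 2, 2), 3.0)
        rng = np.random.default_rng(6)
        tc1 = rng.standard_normal(60)
        tc2 = rng.standard_normal(60)
        data = np.zeros((60, 16))
        labels = np.array([1] * 8 + [2] * 8)
        data[:, :8] = tc1[:, None] + 0.3 * rng.standard_normal((60, 8))
        data[:, 8:] = tc2[:, None] + 0.3 * rng.standard_normal((60, 8))
        parc = _parc(labels, geom)
        assert local_dcbc([_series(data, geom)], parc, geom, 1, 2) > 0

    def test_arbitrary_split_of_one_region_is_near_null(self):
        geom = generate_geometry((4, 2, 2), 3.0)
        rng = np.random.default_rng(7)
        tc = rng.standard_normal(80)
        data = tc[:, None] + 0.5 * rng.standard_normal((80, 16))
        labels = np.array([1, 2] * 8)  # arbitrary split of homogeneous tissue
        parc = _parc(labels, geom)
        val = local_dcbc([_series(data, geom)], parc, geom, 1, 2)
        # permutation null band
        nulls = []
        for _ in range(200):
            lp = rng.permutation(labels)
            try:
                nulls.append(local_dcbc([_series(data, geom)], _parc(lp, geom),
                                        geom, 1, 2))
            except InvalidArgumentError:
                continue
        lo, hi = np.quantile(nulls, [0.005, 0.995])
        assert lo <= val <= hi

    def test_non_adjacent_pair_rejected(self):
        geom = generate_geometry((5, 1, 1), 2.0)
        rng = np.random.default_rng(8)
        series = [_series(rng.standard_normal((20, 5)), geom)]
        parc = _parc([1, 1, 0, 2, 2], geom)
        with pytest.raises(InvalidArgumentError):
            local_dcbc(series, parc, geom, 1, 2)


class TestNegativeBoundaryReport:
    @pytest.mark.parametrize(
        "n_neg,total,expected",
        [(14, 243, 0.0576), (0, 57, 0.0), (35, 302, 0.1159), (2, 45, 0.0444)],
    )
    def test_proportion_arithmetic(self, n_neg, total, expected):
        vals = np.concatenate([-np.ones(n_neg), np.ones(total - n_neg)]) * 0.1
        tab = pd.DataFrame({
            "region_a": np.arange(total), "region_b": np.arange(total) + 1,
            "n_adjacent_voxel_pairs": 1, "local_dcbc": vals,
        })
        rep = negative_boundary_report(BoundaryTable(table=tab))
        assert rep["proportion_negative"] == pytest.approx(expected, abs=5e-5)
        assert rep["n_negative"] == n_neg
        assert rep["n_boundaries"] == total

    def test_boundary_table_end_to_end(self, planted_dataset):
        series, truth = planted_dataset
        geom = series[0].geometry
        parc = _parc(truth.true_labels, geom)
        bt = boundary_table(series[:3], parc, geom)
        pairs = set(region_adjacency(parc, geom))
        assert set(map(tuple, bt.table[["region_a", "region_b"]].to_numpy())) == pairs
        # planted regions: every boundary should be strongly positive
        rep = negative_boundary_report(bt)
        assert rep["proportion_negative"] == 0.0
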