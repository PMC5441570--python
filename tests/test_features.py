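"""Network feature extraction: correlations, thresholded degrees, supervoxels,
link weights and within-site standardization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import connstab as cs
from connstab.cohort import CohortSample, RunTimeSeries
from connstab.features import (
    FeatureMatrix,
    degrees_thresholded,
    link_descriptors,
    n_link_features,
)


def _samples(n, sites=("site01",), groups=None):
    out = []
    for i in range(n):
        out.append(
            CohortSample(
                subject_id=f"s{i}",
                run_id=1,
                site_id=sites[i % len(sites)],
                group=(groups[i] if groups else "control"),
            )
        )
    return out


class TestCorrelationMatrix:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 2, 3], [1, 2, 3], 1.0),
            ([1, 2, 3], [3, 2, 1], -1.0),
            ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),  # hand-evaluated Pearson
        ],
    )
    def test_pairwise_values(self, x, y, expected):
        corr = cs.correlation_matrix(np.array([x, y], dtype=float))
        assert corr[0, 1] == pytest.approx(expected, abs=1e-12)
        assert corr[1, 0] == corr[0, 1]
        np.testing.assert_allclose(np.diag(corr), 1.0)

    def test_constant_row_flagged_zero(self):
        ts = np.array([[1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0]])
        corr, flags = cs.correlation_matrix(ts, return_flags=True)
        assert flags.tolist() == [True, False]
        assert corr[0, 1] == 0.0
        assert corr[0, 0] == 1.0

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ValueError):
            cs.correlation_matrix(np.ones((2, 2)))


class TestThresholdAndDegrees:
    def test_link_above_threshold(self):
        corr = np.array([[1.0, 0.8], [0.8, 1.0]])
        assert cs.threshold_network(corr, 0.7).n_links == 1

    def test_threshold_is_strict(self):
        corr = np.array([[1.0, 0.7], [0.7, 1.0]])
        assert cs.threshold_network(corr, 0.7).n_links == 0

    def test_identity_has_no_links(self):
        assert cs.threshold_network(np.eye(5), 0.0).n_links == 0

    def test_invalid_cutoff_rejected(self):
        with pytest.raises(ValueError):
            cs.threshold_network(np.eye(2), 1.5)

    def test_absolute_option_counts_negative_links(self):
        corr = np.array([[1.0, -0.9], [-0.9, 1.0]])
        assert cs.threshold_network(corr, 0.7).n_links == 0
        assert cs.threshold_network(corr, 0.7, absolute=True).n_links == 1

    def test_complete_and_path_graph_degrees(self):
        complete = np.ones((4, 4))
        net = cs.threshold_network(complete, 0.5)
        assert cs.degrees(net).tolist() == [3, 3, 3, 3]
        path = np.eye(3)
        path[0, 1] = path[1, 0] = path[1, 2] = path[2, 1] = 0.9
        assert cs.degrees(cs.threshold_network(path, 0.7)).tolist() == [1, 2, 1]

    def test_degree_sum_is_twice_link_count(self, rng):
        corr = cs.correlation_matrix(rng.standard_normal((20, 30)))
        net = cs.threshold_network(corr, 0.2)
        d = cs.degrees(net)
        assert d.sum() == 2 * net.n_links
        np.testing.assert_array_equal(d, net.adjacency.sum(axis=1))

    @pytest.mark.parametrize("d, expected", [(0, 0.0), (9, 1.0), (99, 2.0)])
    def test_log_degree_values(self, d, expected):
        assert cs.log_degree(d) == pytest.approx(expected)

    def test_log_degree_monotone_and_rejects_negative(self):
        vals = cs.log_degree(np.arange(50))
        assert np.all(np.diff(vals) > 0)
        with pytest.raises(ValueError):
            cs.log_degree(-1)

    def test_tiled_degrees_match_naive_full_matrix(self, rng):
        # contract: tiled accumulation equals thresholding the full matrix
        ts = rng.standard_normal((60, 40))
        for c in (0.1, 0.3):
            naive = cs.degrees(cs.threshold_network(cs.correlation_matrix(ts), c))
            tiled = degrees_thresholded(ts, c, tile=7)
            np.testing.assert_array_equal(tiled, naive)


class TestSupervoxels:
    def _full_run(self, grid, T=6, fill=None):
        mask = np.ones(grid, dtype=bool)
        coords = np.argwhere(mask)
        series = np.arange(len(coords) * T, dtype=float).reshape(len(coords), T)
        if fill is not None:
            series = fill(coords, T)
        return RunTimeSeries(node_coords=coords, series=series, mask=mask)

    def test_counting_full_grid(self):
        run = self._full_run((8, 8, 6))
        sup = cs.build_supervoxels(run, (4, 4, 3))
        assert sup.n_nodes == 8

    def test_identical_member_series_preserved(self):
        s = np.array([1.0, 5.0, 2.0, 4.0, 3.0, 0.0])
        run = self._full_run((4, 4, 3), T=6, fill=lambda c, T: np.tile(s, (len(c), 1)))
        sup = cs.build_supervoxels(run, (4, 4, 3))
        assert sup.n_nodes == 1
        np.testing.assert_allclose(sup.series[0], s)

    def test_mean_of_partial_mask(self):
        # only two voxels in-mask (values 1 and 3) -> supervoxel constant 2,
        # but with min_fill low enough to keep the block
        mask = np.zeros((4, 4, 3), dtype=bool)
        mask[0, 0, 0] = mask[0, 0, 1] = True
        coords = np.argwhere(mask)
        series = np.array([[1.0] * 5, [3.0] * 5])
        run = RunTimeSeries(node_coords=coords, series=series, mask=mask)
        sup = cs.build_supervoxels(run, (4, 4, 3), min_fill=0.0)
        assert sup.n_nodes == 1
        np.testing.assert_allclose(sup.series[0], 2.0)
        # default min_fill=0.5 drops the nearly-empty block
        with pytest.raises(ValueError):
            cs.build_supervoxels(
                RunTimeSeries(node_coords=coords[:0], series=series[:0], mask=np.zeros((4, 4, 3), bool)),
                (4, 4, 3),
            )
        assert cs.build_supervoxels(run, (4, 4, 3), min_fill=0.5).n_nodes == 0


class TestLinkFeatures:
    @pytest.mark.parametrize("n, expected", [(569, 161596), (2, 1), (4, 6)])
    def test_feature_count(self, n, expected):
        assert n_link_features(n) == expected

    def test_canonical_descriptor_order(self):
        desc = link_descriptors(4)
        assert desc == [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        assert all(i < j for i, j in desc)

    def test_values_match_corr_entries(self, rng):
        corr = cs.correlation_matrix(rng.standard_normal((5, 20)))
        vec = cs.link_weight_features(corr)
        desc = link_descriptors(5)
        for v, (i, j) in zip(vec, desc):
            assert v == corr[i, j]


class TestSiteStandardize:
    def _fm(self, values, sites):
        samples = _samples(len(values), sites=tuple(sites))
        for k, s in enumerate(samples):
            object.__setattr__(s, "site_id", sites[k])
        return FeatureMatrix(
            np.asarray(values, float)[:, None], "link_weight", [(0, 1)], samples
        )

    def test_single_site_z_scores(self):
        fm = self._fm([1.0, 2.0, 3.0], ["a", "a", "a"])
        z = cs.site_standardize(fm)
        np.testing.assert_allclose(z.values[:, 0], [-1.0, 0.0, 1.0])

    def test_location_invariance_across_sites(self):
        fm_a = self._fm([1.0, 2.0, 3.0, 11.0, 12.0, 13.0], ["a"] * 3 + ["b"] * 3)
        z = cs.site_standardize(fm_a)
        np.testing.assert_allclose(z.values[:3, 0], z.values[3:, 0])

    def test_postconditions_on_random_data(self, rng):
        values = rng.standard_normal((30, 8)) * 5 + 2
        sites = ["a"] * 12 + ["b"] * 18
        samples = _samples(30, sites=("x",))
        for k, s in enumerate(samples):
            object.__setattr__(s, "site_id", sites[k])
        fm = FeatureMatrix(values, "link_weight", link_descriptors(8)[:8], samples)
        z = cs.site_standardize(fm)
        for site in ("a", "b"):
            block = z.values[np.array(sites) == site]
            assert np.abs(block.mean(axis=0)).max() < 1e-10
            assert np.abs(block.std(axis=0, ddof=1) - 1).max() < 1e-10

    def test_constant_feature_flagged_zero(self):
        fm = self._fm([2.0, 2.0, 2.0], ["a", "a", "a"])
        z = cs.site_standardize(fm)
        assert z.constant_flags[0]
        np.testing.assert_array_equal(z.values[:, 0], 0.0)

    def test_single_sample_site_rejected(self):
        fm = self._fm([1.0, 2.0, 3.0], ["a", "a", "b"])
        with pytest.raises(ValueError):
            cs.site_standardize(fm)


class TestExtractFeatures:
    def test_shapes_and_determinism(self, small_config, small_cohort):
        samples, runs = small_cohort
        fm = cs.extract_features(runs, samples, "ss_link_weight")
        assert fm.values.shape == (len(samples), n_link_features(8))
        fm2 = cs.extract_features(runs, samples, "ss_link_weight")
        np.testing.assert_array_equal(fm.values, fm2.values)

    def test_degree_matrix_shape(self, small_cohort):
        samples, runs = small_cohort
        fm = cs.extract_features(runs, samples, "log_degree")
        assert fm.values.shape == (len(samples), runs[0].n_nodes)
        assert fm.feature_type == "log_degree"

    def test_planted_link_weight_higher_in_patients(self, small_config, small_link_fm):
        # recovery of the generator's hyperconnectivity direction
        desc = {d: i for i, d in enumerate(small_link_fm.descriptors)}
        pat = small_link_fm.is_patient
        for link in small_config.planted_links:
            col = small_link_fm.values[:, desc[link]]
            assert col[pat].mean() > col[~pat].mean()

    def test_inconsistent_nodes_rejected(self, small_cohort):
        samples, runs = small_cohort
        bad = RunTimeSeries(
            node_coords=runs[0].node_coords[:-1],
            series=runs[0].series[:-1],
            mask=runs[0].mask,
        )
        with pytest.raises(ValueError):
            cs.extract_features([runs[0], bad], samples[:2], "log_degree")


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=2, max_value=40))
def test_link_descriptor_count_matches_formula(n):
    assert len(link_descriptors(n)) == n_link_features(n) == n * (n - 1) // 2
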