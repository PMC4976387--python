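"""Thresholding, occupancy tables, mutual independence, exceedance sweep."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from remikit import (SceneConfig, build_occupancy_table,
                     chi2_mutual_independence, exceedance_sweep,
                     generate_scene, otsu_threshold, percentile_threshold,
                     render_round)
from remikit.occupancy import DEFAULT_SWEEP_PERCENTILES, default_subsets
from _oracles import otsu_oracle_cuts


class TestOtsu:
    def test_bimodal_threshold_separates_modes(self):
        img = np.concatenate([np.full(500, 10.0), np.full(500, 200.0)])
        t = otsu_threshold(img)
        assert 10 < t < 200

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            otsu_threshold(np.full((8, 8), 3.0))

    @pytest.mark.parametrize("seed", range(50))
    def test_equals_exhaustive_intraclass_variance_minimum(self, seed):
        r = np.random.default_rng(seed)
        data = np.concatenate([
            r.normal(r.uniform(20, 80), r.uniform(5, 20), r.integers(500, 3000)),
            r.normal(r.uniform(120, 250), r.uniform(5, 40), r.integers(500, 3000)),
        ])
        t = otsu_threshold(data)
        cuts = otsu_oracle_cuts(data)
        assert np.any(np.isclose(t, cuts, rtol=1e-9))

    def test_symmetric_mixture_threshold_near_midpoint(self):
        # equal-weight, equal-sigma overlapping modes: the intra-class
        # variance minimum sits at the symmetry midpoint
        r = np.random.default_rng(42)
        data = np.concatenate([r.normal(50, 40, 20000), r.normal(200, 40, 20000)])
        t = otsu_threshold(data)
        bin_width = (data.max() - data.min()) / 256
        assert abs(t - 125.0) < bin_width


class TestPercentileThreshold:
    def test_median_convention_on_1_to_100(self):
        values = np.arange(1, 101, dtype=float)
        t = percentile_threshold(values, 0.5)
        assert t == 52.0
        assert (values < t).sum() == 51  # ties resolve toward more below

    def test_sweep_default_endpoints(self):
        assert DEFAULT_SWEEP_PERCENTILES[0] == pytest.approx(0.01)
        assert DEFAULT_SWEEP_PERCENTILES[-1] == pytest.approx(0.95)

    def test_heavily_tied_data_clears_the_tie_run(self):
        values = np.concatenate([np.zeros(80), np.arange(1, 21, dtype=float)])
        t = percentile_threshold(values, 0.5)
        assert 0 < t <= 1
        assert (values < t).mean() == 0.8

    @pytest.mark.parametrize("p", [-0.1, 0.0, 1.0, 1.5])
    def test_out_of_range_percentile_rejected(self, p):
        with pytest.raises(ValueError):
            percentile_threshold(np.arange(10.0), p)

    @given(st.integers(0, 10 ** 6), st.floats(0.01, 0.95))
    def test_fraction_below_exceeds_request(self, seed, p):
        r = np.random.default_rng(seed)
        values = np.floor(r.random(200) * 8)  # heavily quantized
        t = percentile_threshold(values, p)
        frac = (values < t).mean()
        assert frac > p or frac == 1.0


class TestOccupancyTable:
    def test_hand_counted_two_channel_example(self):
        m0 = np.array([[1, 0], [0, 0]], dtype=bool)
        m1 = np.array([[1, 0], [0, 1]], dtype=bool)
        table = build_occupancy_table([m0, m1])
        assert table.n_pixels == 4
        # patterns ordered 00, 01, 10, 11 with channel 0 the high bit
        np.testing.assert_array_equal(table.counts, [2, 1, 0, 1])
        assert table.marginal_occupied(0) == 1
        assert table.marginal_occupied(1) == 2

    def test_all_false_masks_pile_in_zero_pattern(self):
        masks = [np.zeros((5, 5), bool) for _ in range(3)]
        table = build_occupancy_table(masks)
        assert table.counts[0] == 25 and table.counts[1:].sum() == 0

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            build_occupancy_table([np.zeros((4, 4), bool)])

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_counts_match_per_pixel_tally_oracle(self, rng, k):
        masks = [rng.random((15, 15)) > 0.5 for _ in range(k)]
        valid = rng.random((15, 15)) > 0.2
        table = build_occupancy_table(masks, valid=valid)
        oracle = np.zeros(2 ** k, dtype=int)
        for i in range(15):
            for j in range(15):
                if not valid[i, j]:
                    continue
                pattern = 0
                for m in masks:
                    pattern = (pattern << 1) | int(m[i, j])
                oracle[pattern] += 1
        np.testing.assert_array_equal(table.counts, oracle)
        assert table.counts.sum() == valid.sum()


class TestChi2MutualIndependence:
    def test_three_channels_have_four_degrees_of_freedom(self, rng):
        masks = [rng.random((30, 30)) > 0.5 for _ in range(3)]
        res = chi2_mutual_independence(build_occupancy_table(masks))
        assert res.df == 4

    @pytest.mark.parametrize("k", [2, 3, 4, 5, 6])
    def test_df_is_free_cells_minus_marginals(self, k):
        # 2^k - 1 free cells, k fitted marginal probabilities
        from remikit.occupancy import OccupancyTable
        counts = np.ones(2 ** k, dtype=int)
        table = OccupancyTable(k=k, counts=counts, n_pixels=2 ** k,
                               channel_names=tuple(f"c{i}" for i in range(k)))
        res = chi2_mutual_independence(table)
        assert res.df == 2 ** k - 1 - k

    def test_exactly_independent_counts_give_zero_statistic(self):
        from remikit.occupancy import OccupancyTable
        # joint counts that factor exactly: p0 = 0.5, p1 = 0.25, n = 64
        counts = np.array([24, 8, 24, 8])  # 00, 01, 10, 11
        table = OccupancyTable(k=2, counts=counts, n_pixels=64,
                               channel_names=("a", "b"))
        res = chi2_mutual_independence(table)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_two_by_two_hand_oracle(self):
        from remikit.occupancy import OccupancyTable
        # marginals 50/50 -> expected 25 per cell -> statistic 4.0, df 1
        counts = np.array([30, 20, 20, 30])  # 00, 01, 10, 11
        table = OccupancyTable(k=2, counts=counts, n_pixels=100,
                               channel_names=("a", "b"))
        res = chi2_mutual_independence(table)
        assert res.statistic == pytest.approx(4.0)
        assert res.df == 1
        assert res.p_value == pytest.approx(stats.chi2.sf(4.0, 1))

    def test_degenerate_marginal_rejected(self):
        masks = [np.ones((6, 6), bool), np.random.default_rng(0).random((6, 6)) > 0.5]
        with pytest.raises(ValueError, match="degenerate"):
            chi2_mutual_independence(build_occupancy_table(masks))

    def test_low_expected_cells_warn(self):
        from remikit.occupancy import OccupancyTable
        counts = np.array([97, 1, 1, 1])
        table = OccupancyTable(k=2, counts=counts, n_pixels=100,
                               channel_names=("a", "b"))
        res = chi2_mutual_independence(table)
        assert res.warnings


class TestExceedance:
    def test_engineered_parity_independence_gives_unit_ratio(self):
        rows, cols = np.indices((40, 40))
        im0 = (rows % 2 == 0) * 100.0
        im1 = (cols % 2 == 0) * 100.0
        curve = exceedance_sweep([im0, im1],
                                 percentiles=[0.1, 0.25, 0.4],
                                 subsets=[(0, 1)])
        np.testing.assert_allclose(curve.ratios[(0, 1)], 1.0, atol=1e-12)

    def test_unreachable_percentile_recorded_as_missing(self):
        rows, cols = np.indices((40, 40))
        im0 = (rows % 2 == 0) * 100.0
        im1 = (cols % 2 == 0) * 100.0
        curve = exceedance_sweep([im0, im1], percentiles=[0.6, 0.9],
                                 subsets=[(0, 1)])
        assert np.isnan(curve.ratios[(0, 1)]).all()

    def test_identical_channels_match_counting_oracle(self, rng):
        img = rng.random((50, 50)) * 100
        curve = exceedance_sweep([img, img, img], percentiles=[0.3, 0.7],
                                 subsets=[(0, 1), (0, 1, 2)])
        for j, p in enumerate([0.3, 0.7]):
            t = percentile_threshold(img, p)
            occ = (img >= t).mean()
            np.testing.assert_allclose(curve.ratios[(0, 1)][j], 1 / occ)
            np.testing.assert_allclose(curve.ratios[(0, 1, 2)][j], 1 / occ ** 2)
            assert curve.ratios[(0, 1, 2)][j] >= 1.0

    def test_empty_subsets_rejected(self, rng):
        with pytest.raises(ValueError):
            exceedance_sweep([rng.random((8, 8)), rng.random((8, 8))],
                             subsets=[])

    def test_default_subsets_are_pairs_plus_full_set(self):
        assert default_subsets(3) == ((0, 1), (0, 2), (1, 2), (0, 1, 2))
        assert default_subsets(2) == ((0, 1),)

    def test_colocalized_domains_rank_triple_above_pairs(self):
        # planted three-way domain structure: the triple outpaces doublets
        cfg = SceneConfig(channel_affinities=(0.9, 0.9, 0.9), seed=3)
        stack = render_round(generate_scene(cfg), cfg, 1)
        curve = exceedance_sweep(list(stack))
        triple = curve.ratios[(0, 1, 2)]
        upper = curve.percentiles >= 0.5
        assert np.nanmin(triple[upper]) > 1.0
        for pair in ((0, 1), (0, 2), (1, 2)):
            assert np.all(triple[upper] > curve.ratios[pair][upper])
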