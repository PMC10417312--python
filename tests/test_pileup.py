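"""Observed/expected windows, grid rescaling, pileups, relative insulation."""

import numpy as np
import pytest

from hicdelta import ContactMap, GenomeModel, IntervalSet, expected_by_distance
from hicdelta.pileup import (
    PileupConfig,
    PileupResult,
    oe_window,
    pileup_anchors,
    pileup_regions,
    relative_insulation,
    rescale_grid,
)

from conftest import make_random_map


def constant_diagonal_map(n=300, bin_size=10_000):
    g = GenomeModel(("c1",), (n * bin_size,), bin_size)
    s = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    return ContactMap(g, {"c1": 1.0 / (s + 1.0)})


class TestOeWindow:
    def test_map_equal_to_own_expected_gives_unit_oe(self):
        m = constant_diagonal_map(n=100)
        exp = expected_by_distance(m)
        w = oe_window(m, "c1", 100_000, 400_000, exp)
        np.testing.assert_allclose(w, 1.0)

    def test_uniform_map_uniform_expected(self):
        g = GenomeModel(("c1",), (1000,), 100)
        m = ContactMap(g, {"c1": np.full((10, 10), 3.0)})
        w = oe_window(m, "c1", 0, 1000, expected_by_distance(m))
        np.testing.assert_allclose(w, 1.0)

    def test_matches_elementwise_division_brute_force(self):
        g = GenomeModel(("c1",), (5000,), 100)
        m = make_random_map(g, seed=13)
        exp = expected_by_distance(m)
        b0, b1 = 10, 30
        w = oe_window(m, "c1", b0 * 100, b1 * 100, exp)
        for i in range(b0, b1):
            for j in range(b0, b1):
                e = exp["c1"][abs(i - j)]
                if e > 0:
                    assert w[i - b0, j - b0] == m.cis["c1"][i, j] / e
                else:
                    assert np.isnan(w[i - b0, j - b0])

    def test_off_chromosome_window_raises(self):
        m = constant_diagonal_map(n=50)
        with pytest.raises(ValueError, match="off the chromosome"):
            oe_window(m, "c1", -10_000, 100_000, expected_by_distance(m))


class TestRescaleGrid:
    def test_constant_matrix_stays_constant(self):
        out = rescale_grid(np.full((30, 30), 2.5), 9)
        np.testing.assert_allclose(out, 2.5)

    def test_checkerboard_block_means_to_ones(self):
        cb = np.indices((4, 4)).sum(axis=0) % 2 * 2.0
        np.testing.assert_allclose(rescale_grid(cb, 2), 1.0)

    def test_mean_preserved_on_divisible_fully_valid_input(self):
        rng = np.random.default_rng(7)
        m = rng.random((44, 44))
        out = rescale_grid(m, 11)
        assert out.mean() == pytest.approx(m.mean(), abs=1e-9)

    def test_masked_pixels_excluded_from_block_means(self):
        m = np.ones((4, 4))
        m[0, 0] = np.nan
        m[0, 1] = 3.0
        out = rescale_grid(m, 2)
        assert out[0, 0] == pytest.approx((3.0 + 1.0 + 1.0) / 3)

    def test_all_masked_input_gives_all_masked_output(self):
        out = rescale_grid(np.full((4, 4), np.nan), 2)
        assert np.isnan(out).all()


@pytest.fixture(scope="module")
def planted_pileups(planted_sim):
    cfg = PileupConfig(resolution_bp=100_000)
    rc = pileup_regions(planted_sim.control, planted_sim.truth_regions, cfg)
    rt = pileup_regions(planted_sim.treated, planted_sim.truth_regions, cfg)
    return rc, rt


class TestPileupRegions:
    def test_single_region_is_identity(self, planted_sim):
        cfg = PileupConfig(resolution_bp=100_000)
        one = IntervalSet.from_records([tuple(planted_sim.truth_regions.df.iloc[0][:4])])
        res_one = pileup_regions(planted_sim.control, one, cfg)
        assert res_one.n_stacked == 1
        # stacking the same region twice changes nothing (mean linearity)
        two = IntervalSet.from_records(
            [tuple(planted_sim.truth_regions.df.iloc[0][:4])] * 2
        )
        res_two = pileup_regions(planted_sim.control, two, cfg)
        np.testing.assert_allclose(res_one.grid, res_two.grid, equal_nan=True)

    def test_control_map_shows_tad_block_enrichment(self, planted_pileups):
        """Within-TAD bands of the grid exceed the between-TAD rectangle."""
        rc, _ = planted_pileups
        c0, c1 = rc.region_span_cols
        mid = (c0 + c1) // 2
        intra = np.concatenate(
            [rc.grid[c0:mid, c0:mid].ravel(), rc.grid[mid:c1, mid:c1].ravel()]
        )
        inter = rc.grid[c0:mid, mid:c1].ravel()
        assert np.nanmean(intra) > np.nanmean(inter)

    def test_between_band_ratio_recovers_delta(self, planted_pileups, planted_sim):
        rc, rt = planted_pileups
        c0, c1 = rc.region_span_cols
        mid = (c0 + c1) // 2
        ratio = np.nanmean(rt.grid[c0:mid, mid:c1]) / np.nanmean(rc.grid[c0:mid, mid:c1])
        assert ratio == pytest.approx(planted_sim.config.delta, abs=0.1)

    def test_all_regions_skipped_is_hard_error(self, planted_sim):
        cfg = PileupConfig(resolution_bp=100_000)
        edge = IntervalSet.from_records([("chrS1", 0, 500_000)])  # flank falls off
        with pytest.raises(ValueError, match="no usable regions"):
            pileup_regions(planted_sim.control, edge, cfg)


class TestPileupAnchors:
    def test_single_anchor_is_that_window(self):
        m = constant_diagonal_map(n=400)
        cfg = PileupConfig(mode="fixed_anchor", flank_bp=200_000, resolution_bp=10_000)
        anchors = IntervalSet.from_records([("c1", 2_000_000, 2_000_001)])
        res = pileup_anchors(m, anchors, cfg)
        direct = oe_window(m, "c1", 1_800_000, 2_210_000, expected_by_distance(m))
        np.testing.assert_allclose(res.grid, direct)

    def test_translation_invariance_on_constant_diagonal_map(self):
        m = constant_diagonal_map(n=400)
        cfg = PileupConfig(mode="fixed_anchor", flank_bp=200_000, resolution_bp=10_000)
        a = pileup_anchors(m, IntervalSet.from_records([("c1", 1_000_000, 1_000_001)]), cfg)
        b = pileup_anchors(m, IntervalSet.from_records([("c1", 1_010_000, 1_010_001)]), cfg)
        np.testing.assert_allclose(a.grid, b.grid)

    def test_boundary_anchors_show_cross_quadrant_depletion(self, planted_sim):
        cfg = PileupConfig(mode="fixed_anchor", flank_bp=500_000, resolution_bp=100_000)
        bounds = []
        for chrom, doms in planted_sim.config.tad_partition.items():
            for _, e in doms[2:-2]:
                bounds.append((chrom, e * 100_000, e * 100_000 + 1))
        res = pileup_anchors(planted_sim.control, IntervalSet.from_records(bounds), cfg)
        n = res.grid.shape[0]
        mid = n // 2
        cross = np.nanmean(res.grid[:mid, mid + 1 :])
        within = np.nanmean(
            np.concatenate([res.grid[:mid, :mid].ravel(), res.grid[mid + 1 :, mid + 1 :].ravel()])
        )
        assert cross < within

    def test_all_clipped_anchors_is_hard_error(self):
        m = constant_diagonal_map(n=50)
        cfg = PileupConfig(mode="fixed_anchor", flank_bp=1_000_000, resolution_bp=10_000)
        with pytest.raises(ValueError, match="clipped"):
            pileup_anchors(m, IntervalSet.from_records([("c1", 0, 1)]), cfg)


class TestRelativeInsulation:
    def grid_result(self, grid):
        return PileupResult(grid=grid, n_stacked=1, region_span_cols=(0, grid.shape[0]))

    def test_uniform_grid_gives_zero(self):
        assert relative_insulation(self.grid_result(np.ones((20, 20)))) == 0.0

    def test_two_versus_one_quadrants_give_one(self):
        g = np.ones((20, 20))
        g[:10, :10] = 2.0
        g[10:, 10:] = 2.0
        assert relative_insulation(self.grid_result(g)) == pytest.approx(1.0)

    def test_antisymmetric_under_block_swap(self):
        rng = np.random.default_rng(3)
        g = np.ones((20, 20))
        g[:10, :10] = g[10:, 10:] = 1.0 + rng.random()
        g[:10, 10:] = g[10:, :10] = 1.0 + rng.random()
        swapped = g.copy()
        swapped[:10, :10], swapped[:10, 10:] = g[:10, 10:].copy(), g[:10, :10].copy()
        swapped[10:, 10:], swapped[10:, :10] = g[10:, :10].copy(), g[10:, 10:].copy()
        ri_a = relative_insulation(self.grid_result(g))
        ri_b = relative_insulation(self.grid_result(swapped))
        assert ri_a == pytest.approx(-ri_b)

    def test_empty_quadrant_reports_na(self):
        g = np.full((20, 20), np.nan)
        assert np.isnan(relative_insulation(self.grid_result(g)))

    def test_treated_gains_insulation_on_planted_fixture(self, planted_pileups):
        rc, rt = planted_pileups
        assert rt.relative_insulation > rc.relative_insulation
        gain = rt.relative_insulation - rc.relative_insulation
        assert gain == pytest.approx(1.0, abs=0.15)  # -log2(delta)
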