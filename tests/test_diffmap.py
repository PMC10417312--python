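"""Sum scaling, the masked log2-ratio map, and the coverage control."""

import numpy as np
import pytest

from hicdelta import (
    ContactMap,
    GenomeModel,
    IntervalSet,
    coverage_report,
    log2_ratio,
    overall_sum,
    scale_map,
)
from hicdelta.simulate import build_expected, demo_config

from conftest import make_random_map


def three_bin_map():
    g = GenomeModel(("c1",), (300,), 100)
    m = np.zeros((3, 3))
    m[0, 1] = m[1, 0] = 2
    m[1, 2] = m[2, 1] = 4
    m[0, 0] = 9
    return ContactMap(g, {"c1": m})


class TestOverallSum:
    def test_direct_sum_excludes_diagonal(self):
        assert overall_sum(three_bin_map()) == 6

    def test_diagonal_only_map_cannot_scale(self):
        g = GenomeModel(("c1",), (300,), 100)
        m = ContactMap(g, {"c1": np.diag([1.0, 2.0, 3.0])})
        with pytest.raises(ValueError, match="zero"):
            overall_sum(m)

    def test_matches_brute_force_pixel_loop(self):
        g = GenomeModel(("c1", "c2", "cX"), (1500, 1000, 800), 100, (True, True, False))
        m = make_random_map(g, seed=8)
        m.trans = {
            ("c1", "c2"): np.arange(150.0).reshape(15, 10),
            ("c2", "cX"): np.full((10, 8), 2.0),  # involves non-autosome: excluded
        }
        m = ContactMap(g, m.cis, m.trans)
        brute = 0.0
        for chrom in ("c1", "c2"):  # autosomes only
            block = m.cis[chrom]
            n = block.shape[0]
            for i in range(n):
                for j in range(i + 1, n):
                    brute += block[i, j]
        brute += m.trans[("c1", "c2")].sum()
        assert overall_sum(m) == brute

    def test_non_autosome_cis_excluded(self):
        g = GenomeModel(("c1", "cX"), (300, 300), 100, (True, False))
        cis = {"c1": np.zeros((3, 3)), "cX": np.zeros((3, 3))}
        cis["c1"][0, 1] = cis["c1"][1, 0] = 5
        cis["cX"][0, 2] = cis["cX"][2, 0] = 100
        assert overall_sum(ContactMap(g, cis)) == 5


class TestScaleMap:
    def test_scale_invariance_under_depth(self):
        m = three_bin_map()
        s1 = scale_map(m)
        s2 = scale_map(m.scaled_by(7.3))
        np.testing.assert_allclose(s1.cis["c1"], s2.cis["c1"])

    def test_three_bin_example(self):
        s = scale_map(three_bin_map())
        assert s.cis["c1"][0, 1] == pytest.approx(2 / 6)

    def test_scaled_map_has_unit_overall_sum(self):
        g = GenomeModel(("c1", "c2"), (3000, 2000), 100)
        m = make_random_map(g, seed=4)
        assert overall_sum(scale_map(m)) == pytest.approx(1.0, abs=1e-12)


class TestLog2Ratio:
    def test_identity_gives_zero_everywhere_valid(self):
        m = three_bin_map()
        d = log2_ratio(m, m)
        assert (d.values["c1"][d.mask["c1"]] == 0).all()

    def test_depth_difference_cancels(self):
        m = three_bin_map()
        d = log2_ratio(m.scaled_by(2.0), m)
        assert (d.values["c1"][d.mask["c1"]] == 0).all()

    def test_antisymmetry_between_orders(self):
        g = GenomeModel(("c1",), (3000,), 100)
        a = make_random_map(g, seed=1)
        b = make_random_map(g, seed=2)
        dab = log2_ratio(a, b)
        dba = log2_ratio(b, a)
        np.testing.assert_array_equal(dab.mask["c1"], dba.mask["c1"])
        m = dab.mask["c1"]
        np.testing.assert_allclose(dab.values["c1"][m], -dba.values["c1"][m])

    def test_mask_policy_yields_no_nonfinite_values(self):
        g = GenomeModel(("c1",), (3000,), 100)
        d = log2_ratio(make_random_map(g, seed=5), make_random_map(g, seed=6))
        assert np.isfinite(d.values["c1"][d.mask["c1"]]).all()
        # zero pixels in either raw map are masked
        assert not d.mask["c1"][(make_random_map(g, seed=5).cis["c1"] == 0)].any()

    def test_pseudocount_policy_marks_all_pixels_valid(self):
        g = GenomeModel(("c1",), (3000,), 100)
        d = log2_ratio(
            make_random_map(g, seed=5), make_random_map(g, seed=6), zero_policy="pseudocount"
        )
        assert d.mask["c1"].all()
        assert np.isfinite(d.values["c1"]).all()

    def test_genome_mismatch_is_hard_error(self):
        a = three_bin_map()
        b = make_random_map(GenomeModel(("c1",), (400,), 100), seed=1)
        with pytest.raises(ValueError, match="genome"):
            log2_ratio(a, b)

    def test_planted_rectangle_mean_matches_expected_matrix_oracle(self, planted_sim):
        """Mean log2 ratio over planted rectangles ~ log2(delta) = -1."""
        cfg = planted_sim.config
        d = log2_ratio(planted_sim.treated, planted_sim.control)
        ec = build_expected(cfg, "control")
        et = build_expected(cfg, "treated")
        vals, oracle = [], []
        for chrom, i in cfg.planted_pairs:
            (a1, b1), (a2, b2) = cfg.tad_partition[chrom][i : i + 2]
            rect_m = d.mask[chrom][a1:b1, a2:b2]
            vals.append(d.values[chrom][a1:b1, a2:b2][rect_m])
            oracle.append(np.log2(et[chrom][a1:b1, a2:b2] / ec[chrom][a1:b1, a2:b2]))
        measured = float(np.concatenate(vals).mean())
        expected = float(np.concatenate([o.ravel() for o in oracle]).mean())
        assert expected == pytest.approx(-1.0)
        assert measured == pytest.approx(expected, abs=0.15)


class TestCoverageReport:
    def test_identity_maps_have_zero_ratios(self):
        m = three_bin_map()
        regions = IntervalSet.from_records([("c1", 0, 300, "r0")])
        rep = coverage_report(m, m, regions)
        assert rep.regions["mean_log2_scaled"].abs().max() == 0

    def test_empty_regions_logged_not_fatal(self, caplog):
        import logging

        m = three_bin_map()
        with caplog.at_level(logging.WARNING):
            rep = coverage_report(m, m, IntervalSet())
        assert len(rep.regions) == 0

    def test_marginals_equal_row_sums(self):
        g = GenomeModel(("c1",), (3000,), 100)
        m = make_random_map(g, seed=9)
        rep = coverage_report(m, m)
        np.testing.assert_array_equal(
            rep.marginals_raw["c1"]["control"].to_numpy(), m.cis["c1"].sum(axis=1)
        )

    def test_redistribution_only_fixture_stays_level(self, planted_sim):
        """Planted depletion redistributes contacts; marginals barely move."""
        rep = coverage_report(
            planted_sim.control, planted_sim.treated, planted_sim.truth_regions
        )
        assert rep.regions["mean_log2_scaled"].abs().max() < 0.15

    def test_row_doubling_shifts_that_marginal_by_one(self):
        """Analytic perturbation on a noiseless expected-matrix map."""
        cfg = demo_config()
        E = build_expected(cfg, "control")
        control = ContactMap(cfg.genome, {c: e.copy() for c, e in E.items()})
        treated = control.copy()
        k = 100
        treated.cis["chrS1"][k] *= 2
        treated.cis["chrS1"][:, k] *= 2
        treated.cis["chrS1"][k, k] = 2 * control.cis["chrS1"][k, k]
        treated = ContactMap(cfg.genome, treated.cis)
        rep = coverage_report(control, treated)
        raw_ratio = np.log2(
            rep.marginals_raw["chrS1"]["treated"].to_numpy()
            / rep.marginals_raw["chrS1"]["control"].to_numpy()
        )
        assert raw_ratio[k] == pytest.approx(1.0, abs=1e-9)
        # bins in the same TAD share large near-diagonal pixels with bin k and
        # shift slightly; bins beyond the TAD span are essentially untouched
        far = np.abs(np.arange(len(raw_ratio)) - k) > 10
        assert np.abs(raw_ratio[far]).max() < 0.02
        assert np.abs(np.delete(raw_ratio, k)).max() < 0.5 * raw_ratio[k]
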