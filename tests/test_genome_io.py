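"""Genome bookkeeping, contact-map TSV round trips, BED I/O, bin masks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hicdelta import (
    ContactMap,
    GenomeModel,
    IntervalSet,
    intervals_to_bins,
    read_bed,
    read_contact_tsv,
    write_bed,
    write_contact_tsv,
)
from hicdelta.contacts import read_cool

from conftest import make_random_map


class TestGenomeModel:
    def test_bin_counts_use_ceiling_division(self):
        g = GenomeModel(("c1", "c2"), (1050, 1000), 100)
        assert g.n_bins("c1") == 11  # last partial bin retained
        assert g.n_bins("c2") == 10
        assert g.total_bins == 21

    @given(st.integers(min_value=0, max_value=20))
    @settings(deadline=None, max_examples=25)
    def test_bin_id_locus_bijection(self, bin_id):
        g = GenomeModel(("c1", "c2"), (1050, 1000), 100)
        chrom, start = g.bin_locus(bin_id)
        assert g.bin_id(chrom, start) == bin_id

    def test_validation_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            GenomeModel(("c1",), (0,), 100)
        with pytest.raises(ValueError):
            GenomeModel(("c1",), (100,), 0)
        with pytest.raises(ValueError):
            GenomeModel(("c1", "c1"), (100, 100), 10)

    def test_autosome_flags(self):
        g = GenomeModel(("c1", "cX"), (1000, 1000), 100, (True, False))
        assert g.autosomes == ("c1",)


class TestContactTsv:
    def test_single_pixel_is_mirrored(self, tmp_path):
        g = GenomeModel(("c1",), (300,), 100)
        p = tmp_path / "m.tsv"
        p.write_text("c1\t0\tc1\t1\t5\n")
        m = read_contact_tsv(p, g)
        assert m.cis["c1"][0, 1] == 5 and m.cis["c1"][1, 0] == 5
        assert m.cis["c1"].sum() == 10

    def test_empty_file_gives_zero_map(self, tmp_path):
        g = GenomeModel(("c1", "c2"), (300, 200), 100)
        p = tmp_path / "m.tsv"
        p.write_text("")
        m = read_contact_tsv(p, g)
        assert m.cis["c1"].shape == (3, 3) and not m.cis["c1"].any()
        assert m.cis["c2"].shape == (2, 2) and not m.cis["c2"].any()

    @pytest.mark.parametrize(
        "line,match",
        [
            ("cZ\t0\tc1\t1\t5", "unknown chromosome"),
            ("c1\t0\tc1\t1\t-2", "negative count"),
            ("c1\t0\tc1\t1\t5\nc1\t1\tc1\t0\t3", "duplicate pixel"),
        ],
    )
    def test_hard_errors_name_the_line(self, tmp_path, line, match):
        g = GenomeModel(("c1",), (300,), 100)
        p = tmp_path / "m.tsv"
        p.write_text(line + "\n")
        with pytest.raises(ValueError, match=match):
            read_contact_tsv(p, g)

    def test_round_trip_reproduces_every_pixel(self, tmp_path):
        g = GenomeModel(("c1",), (5000,), 100)  # 50 bins
        m = make_random_map(g, seed=11)
        p = tmp_path / "m.tsv"
        write_contact_tsv(m, p)
        m2 = read_contact_tsv(p, g)
        np.testing.assert_array_equal(m.cis["c1"], m2.cis["c1"])

    def test_write_read_write_is_byte_identical(self, tmp_path):
        g = GenomeModel(("c1", "c2"), (3000, 2000), 100)
        m = make_random_map(g, seed=3)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_contact_tsv(m, p1)
        write_contact_tsv(read_contact_tsv(p1, g), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_all_zero_map_writes_header_only(self, tmp_path):
        g = GenomeModel(("c1",), (300,), 100)
        p = tmp_path / "z.tsv"
        write_contact_tsv(ContactMap(g, {}), p)
        lines = p.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("#")

    def test_trans_pixels_round_trip(self, tmp_path):
        g = GenomeModel(("c1", "c2"), (300, 200), 100)
        trans = {("c1", "c2"): np.array([[0.0, 7.0], [1.0, 0.0], [0.0, 0.0]])}
        m = ContactMap(g, {}, trans)
        p = tmp_path / "t.tsv"
        write_contact_tsv(m, p)
        m2 = read_contact_tsv(p, g)
        np.testing.assert_array_equal(m2.trans[("c1", "c2")], trans[("c1", "c2")])

    def test_asymmetric_block_rejected(self):
        g = GenomeModel(("c1",), (200,), 100)
        with pytest.raises(ValueError, match="symmetric"):
            ContactMap(g, {"c1": np.array([[0.0, 1.0], [2.0, 0.0]])})


class TestBed:
    def test_basic_interval_and_track_header(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("track name=x\n# comment\nc1\t0\t100\n")
        iv = read_bed(p)
        assert len(iv) == 1
        chrom, start, end, *_ = next(iter(iv))
        assert (chrom, start, end) == ("c1", 0, 100)

    def test_round_trip_preserves_records(self, tmp_path):
        iv = IntervalSet.from_records(
            [("c2", 50, 150, "b", 3.5), ("c1", 0, 100, "a", 1), ("c1", 200, 300, "c", 0)]
        ).sort()
        p = tmp_path / "a.bed"
        write_bed(iv, p)
        iv2 = read_bed(p)
        assert iv.df.equals(iv2.df)

    @pytest.mark.parametrize("bad", ["c1\t100\t100", "c1\tx\t200"])
    def test_invalid_records_raise_with_line_number(self, tmp_path, bad):
        p = tmp_path / "a.bed"
        p.write_text(bad + "\n")
        with pytest.raises(ValueError, match=":1"):
            read_bed(p)


class TestIntervalsToBins:
    def test_single_bin_boundary(self, toy_genome):
        masks = intervals_to_bins(
            IntervalSet.from_records([("c1", 0, 100)]), toy_genome
        )
        assert masks["c1"][0] and not masks["c1"][1:].any()

    def test_straddling_interval_marks_both_bins(self, toy_genome):
        masks = intervals_to_bins(
            IntervalSet.from_records([("c1", 99, 101)]), toy_genome
        )
        assert masks["c1"][0] and masks["c1"][1] and not masks["c1"][2:].any()

    def test_matches_per_bp_brute_force(self, toy_genome):
        rng = np.random.default_rng(42)
        starts = rng.integers(0, 1990, size=100)
        ends = starts + rng.integers(1, 400, size=100)
        ends = np.minimum(ends, 2000)
        iv = IntervalSet.from_records(
            [("c1", int(s), int(e)) for s, e in zip(starts, ends) if s < e]
        )
        masks = intervals_to_bins(iv, toy_genome)
        covered = np.zeros(2000, dtype=bool)
        for _, s, e, *_ in iv:
            covered[s:e] = True
        brute = np.array([covered[b * 100 : (b + 1) * 100].any() for b in range(20)])
        np.testing.assert_array_equal(masks["c1"], brute)

    def test_interval_past_end_is_clipped(self, toy_genome, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            masks = intervals_to_bins(
                IntervalSet.from_records([("c1", 1900, 2500)]), toy_genome
            )
        assert masks["c1"][19] and not masks["c1"][:19].any()
        assert any("clipping" in r.message for r in caplog.records)


class TestCoolAdapter:
    def test_reads_schema_conformant_file(self, tmp_path):
        import h5py

        g = GenomeModel(("c1", "c2"), (300, 200), 100)
        dense = make_random_map(g, seed=5)
        # build the .cool hierarchy directly: chroms, bins, upper-triangle pixels
        path = tmp_path / "toy.cool"
        n1, n2 = 3, 2
        with h5py.File(path, "w") as f:
            f.create_dataset("chroms/name", data=np.array([b"c1", b"c2"]))
            f.create_dataset("chroms/length", data=np.array([300, 200]))
            chrom_ids = np.array([0] * n1 + [1] * n2)
            starts = np.array([0, 100, 200, 0, 100])
            ends = np.array([100, 200, 300, 100, 200])
            f.create_dataset("bins/chrom", data=chrom_ids)
            f.create_dataset("bins/start", data=starts)
            f.create_dataset("bins/end", data=ends)
            b1, b2, cnt = [], [], []
            for i in range(3):
                for j in range(i, 3):
                    if dense.cis["c1"][i, j]:
                        b1.append(i), b2.append(j), cnt.append(dense.cis["c1"][i, j])
            for i in range(2):
                for j in range(i, 2):
                    if dense.cis["c2"][i, j]:
                        b1.append(3 + i), b2.append(3 + j), cnt.append(dense.cis["c2"][i, j])
            f.create_dataset("pixels/bin1_id", data=np.array(b1))
            f.create_dataset("pixels/bin2_id", data=np.array(b2))
            f.create_dataset("pixels/count", data=np.array(cnt))
        m = read_cool(path)
        np.testing.assert_array_equal(m.cis["c1"], dense.cis["c1"])
        np.testing.assert_array_equal(m.cis["c2"], dense.cis["c2"])
        assert m.genome.bin_size_bp == 100
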