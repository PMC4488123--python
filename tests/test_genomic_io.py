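import numpy as np
import pandas as pd
import pytest

from epifpca import (
    CoverageTrack,
    RegionSet,
    extract_profiles,
    filter_blacklist,
    normalize_track,
    read_bedgraph,
    read_regions,
    write_bedgraph,
)

SIZES = {"chr1": 100_000, "chr2": 50_000}


def bedgraph(tmp_path, text, name="a.bedGraph"):
    p = tmp_path / name
    p.write_text(text)
    return p


def regionset(rows, flank):
    df = pd.DataFrame(rows, columns=["region_id", "chrom", "anchor",
                                     "strand", "class_label"])
    return RegionSet(entries=df, flank=flank)


class TestReadBedgraph:
    def test_single_line_wigsum(self, tmp_path):
        t = read_bedgraph(bedgraph(tmp_path, "chr1\t0\t10\t2.0\n"), SIZES)
        assert t.wigsum == pytest.approx(20.0)

    def test_empty_file(self, tmp_path):
        t = read_bedgraph(bedgraph(tmp_path, ""), SIZES)
        assert t.wigsum == 0 and t.n_intervals == 0

    def test_shuffled_lines_sorted_and_summed(self, tmp_path):
        text = ("chr1\t500\t600\t1.5\n"
                "chr1\t0\t100\t2.0\n"
                "chr1\t200\t300\t0.5\n")
        t = read_bedgraph(bedgraph(tmp_path, text), SIZES)
        s, e, v = t.data["chr1"]
        assert list(s) == [0, 200, 500]
        # hand sum: 2.0*100 + 0.5*100 + 1.5*100
        assert t.wigsum == pytest.approx(400.0)

    def test_track_lines_skipped(self, tmp_path):
        text = ("track type=bedGraph name=x\n"
                "# comment\n"
                "chr1\t0\t10\t1\n")
        t = read_bedgraph(bedgraph(tmp_path, text), SIZES)
        assert t.wigsum == pytest.approx(10.0)

    def test_bookended_equal_values_merged(self, tmp_path):
        text = "chr1\t0\t10\t2\nchr1\t10\t20\t2\nchr1\t20\t30\t1\n"
        t = read_bedgraph(bedgraph(tmp_path, text), SIZES)
        s, e, v = t.data["chr1"]
        assert list(s) == [0, 20] and list(e) == [20, 30]

    def test_overlap_error_names_line(self, tmp_path):
        text = "chr1\t0\t10\t1\nchr1\t5\t15\t1\n"
        with pytest.raises(ValueError, match=":2:"):
            read_bedgraph(bedgraph(tmp_path, text), SIZES)

    def test_unknown_chromosome(self, tmp_path):
        with pytest.raises(ValueError, match="chrZ"):
            read_bedgraph(bedgraph(tmp_path, "chrZ\t0\t10\t1\n"), SIZES)

    def test_non_numeric_value(self, tmp_path):
        with pytest.raises(ValueError, match="malformed"):
            read_bedgraph(bedgraph(tmp_path, "chr1\t0\t10\thigh\n"), SIZES)

    def test_roundtrip_through_writer(self, tmp_path):
        text = ("chr1\t100\t250\t1.25\nchr1\t300\t400\t0.73\n"
                "chr2\t0\t50\t2.125\n")
        t1 = read_bedgraph(bedgraph(tmp_path, text), SIZES)
        out = tmp_path / "out.bedGraph"
        write_bedgraph(t1, out)
        t2 = read_bedgraph(out, SIZES)
        assert list(t1.intervals()) == list(t2.intervals())


class TestNormalize:
    def track(self, value, length):
        return CoverageTrack(chrom_sizes=SIZES,
                             data={"chr1": ([0], [length], [value])})

    def test_identity_when_at_target(self):
        t = normalize_track(self.track(1.0, 100), target_wigsum=100.0)
        assert t.data["chr1"][2][0] == pytest.approx(1.0, rel=1e-12)

    def test_constant_scaling(self):
        # 2.0 over 25 Mb has wigsum 5e7; scaling to 1e8 doubles values
        big = {"chr1": 30_000_000}
        t = CoverageTrack(chrom_sizes=big,
                          data={"chr1": ([0], [25_000_000], [2.0])})
        out = normalize_track(t)
        assert out.data["chr1"][2][0] == pytest.approx(4.0, rel=1e-12)

    def test_random_track_hits_target(self):
        rng = np.random.default_rng(0)
        starts = np.arange(0, 1000, 100)
        t = CoverageTrack(chrom_sizes=SIZES,
                          data={"chr1": (starts, starts + 50,
                                         rng.uniform(0.1, 5, 10))})
        out = normalize_track(t, target_wigsum=1e8)
        assert out.wigsum == pytest.approx(1e8, rel=1e-9)

    def test_idempotent(self):
        t = self.track(3.7, 123)
        once = normalize_track(t)
        twice = normalize_track(once)
        assert np.allclose(once.data["chr1"][2], twice.data["chr1"][2],
                           rtol=1e-9)

    def test_empty_track_error(self):
        t = CoverageTrack(chrom_sizes=SIZES, data={})
        with pytest.raises(ValueError, match="empty track"):
            normalize_track(t)


class TestReadRegions:
    def write(self, tmp_path, rows):
        p = tmp_path / "r.bed"
        p.write_text("".join("\t".join(map(str, r)) + "\n" for r in rows))
        return p

    def test_plus_strand_anchor_is_start(self, tmp_path):
        p = self.write(tmp_path, [("chr1", 1000, 2000, "g1", 0, "+")])
        rs = read_regions(p, flank=500, chrom_sizes=SIZES)
        assert rs.entries.loc[0, "anchor"] == 1000
        w = rs.windows()
        assert (w.loc[0, "start"], w.loc[0, "end"]) == (500, 1500)

    def test_minus_strand_anchor_is_end_minus_one(self, tmp_path):
        p = self.write(tmp_path, [("chr1", 1000, 2000, "g1", 0, "-")])
        rs = read_regions(p, flank=500, chrom_sizes=SIZES)
        assert rs.entries.loc[0, "anchor"] == 1999
        w = rs.windows()
        assert (w.loc[0, "start"], w.loc[0, "end"]) == (1499, 2499)

    def test_out_of_bounds_dropped(self, tmp_path):
        p = self.write(tmp_path, [("chr1", 100, 600, "g1", 0, "+"),
                                  ("chr1", 5000, 6000, "g2", 0, "+")])
        rs = read_regions(p, flank=500, chrom_sizes=SIZES)
        assert rs.region_ids == ["g2"]

    def test_duplicate_anchor_keeps_first(self, tmp_path):
        p = self.write(tmp_path, [("chr1", 1000, 2000, "g1", 0, "+"),
                                  ("chr1", 1000, 3000, "g2", 0, "+")])
        rs = read_regions(p, flank=500, chrom_sizes=SIZES)
        assert rs.region_ids == ["g1"]

    def test_bad_strand(self, tmp_path):
        p = self.write(tmp_path, [("chr1", 1000, 2000, "g1", 0, ".")])
        with pytest.raises(ValueError, match="strand"):
            read_regions(p, flank=500, chrom_sizes=SIZES)

    def test_duplicate_id(self, tmp_path):
        p = self.write(tmp_path, [("chr1", 1000, 2000, "g1", 0, "+"),
                                  ("chr1", 5000, 6000, "g1", 0, "+")])
        with pytest.raises(ValueError, match="duplicate region_id"):
            read_regions(p, flank=500, chrom_sizes=SIZES)

    def test_class_label_column(self, tmp_path):
        p = self.write(tmp_path, [("chr1", 1000, 2000, "g1", 0, "+", "pc")])
        rs = read_regions(p, flank=500, chrom_sizes=SIZES)
        assert rs.entries.loc[0, "class_label"] == "pc"


class TestFilterBlacklist:
    def regions(self):
        return regionset([("g1", "chr1", 1000, "+", ""),
                          ("g2", "chr1", 3000, "+", "")], flank=500)

    def test_one_bp_overlap_removes(self):
        out = filter_blacklist(self.regions(), [("chr1", 1499, 1600)])
        assert out.region_ids == ["g2"]

    def test_half_open_no_overlap_keeps(self):
        out = filter_blacklist(self.regions(), [("chr1", 1500, 1600)])
        assert out.region_ids == ["g1", "g2"]

    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(5)
        rows = [(f"g{i}", "chr1", int(a), "+", "")
                for i, a in enumerate(rng.integers(1000, 90_000, 10))]
        rs = regionset(rows, flank=500)
        bl = [("chr1", 20_000, 25_000), ("chr1", 60_000, 61_000)]
        out = filter_blacklist(rs, bl, exclude_ids=["g0"])
        expected = []
        for rid, chrom, a, s, c in rows:
            if rid == "g0":
                continue
            w0, w1 = a - 500, a + 500
            hit = any(w0 < be and w1 > bs for _, bs, be in bl)
            if not hit:
                expected.append(rid)
        assert out.region_ids == expected

    def test_idempotent_subset(self):
        rs = self.regions()
        bl = [("chr1", 900, 1100)]
        once = filter_blacklist(rs, bl)
        twice = filter_blacklist(once, bl)
        assert once.region_ids == twice.region_ids
        assert set(once.region_ids) <= set(rs.region_ids)


class TestExtractProfiles:
    def constant_track(self, value=3.0):
        return CoverageTrack(chrom_sizes=SIZES,
                             data={"chr1": ([0], [100_000], [value])})

    def test_constant_track_both_strands(self):
        rs = regionset([("p", "chr1", 2000, "+", ""),
                        ("m", "chr1", 5000, "-", "")], flank=100)
        pm = extract_profiles(self.constant_track(), rs, bin_size=10)
        assert pm.values.shape == (2, 20)
        assert np.all(pm.values == 3.0)

    def test_minus_strand_reversal_contract(self):
        # signal in the most-downstream genomic bin of a + region appears in
        # the last column; the same genomic layout on a - region appears in
        # the first column (transcription orientation)
        data = {"chr1": ([2090, 5090], [2100, 5100], [7.0, 7.0])}
        track = CoverageTrack(chrom_sizes=SIZES, data=data)
        rs = regionset([("p", "chr1", 2000, "+", ""),
                        ("m", "chr1", 5000, "-", "")], flank=100)
        pm = extract_profiles(track, rs, bin_size=10)
        assert pm.values[0, -1] == 7.0 and pm.values[0, :-1].sum() == 0
        assert pm.values[1, 0] == 7.0 and pm.values[1, 1:].sum() == 0

    def test_no_reversal_option_keeps_genome_orientation(self):
        data = {"chr1": ([5090], [5100], [7.0])}
        track = CoverageTrack(chrom_sizes=SIZES, data=data)
        rs = regionset([("m", "chr1", 5000, "-", "")], flank=100)
        pm = extract_profiles(track, rs, bin_size=10, reverse_minus=False)
        assert pm.values[0, -1] == 7.0

    def test_bin_means_match_per_base_expansion(self):
        data = {"chr1": ([998, 1003], [1002, 1008], [2.0, 4.0])}
        track = CoverageTrack(chrom_sizes=SIZES, data=data)
        rs = regionset([("g", "chr1", 1000, "+", "")], flank=10)
        pm = extract_profiles(track, rs, bin_size=5)
        base = np.zeros(100_000)
        base[998:1002] = 2.0
        base[1003:1008] = 4.0
        expected = base[990:1010].reshape(4, 5).mean(axis=1)
        assert np.allclose(pm.values[0], expected)

    def test_missing_chromosome_warns_and_zero_fills(self, caplog):
        rs = regionset([("g", "chr9", 2000, "+", "")], flank=100)
        with caplog.at_level("WARNING"):
            pm = extract_profiles(self.constant_track(), rs, bin_size=10)
        assert np.all(pm.values == 0)
        assert "absent" in caplog.text

    def test_strand_flip_invariance_for_symmetric_track(self):
        track = self.constant_track(1.5)
        rows = [("a", "chr1", 2000, "+", ""), ("b", "chr1", 5000, "-", "")]
        flipped = [("a", "chr1", 2000, "-", ""), ("b", "chr1", 5000, "+", "")]
        p1 = extract_profiles(track, regionset(rows, 100), bin_size=10)
        p2 = extract_profiles(track, regionset(flipped, 100), bin_size=10)
        assert np.allclose(p1.values, p2.values)

    def test_flank_not_divisible(self):
        rs = regionset([("g", "chr1", 2000, "+", "")], flank=101)
        with pytest.raises(ValueError, match="divisible"):
            extract_profiles(self.constant_track(), rs, bin_size=10)
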