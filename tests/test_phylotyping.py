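"""Classification, demultiplexing, binning, dominance and summaries."""

import math

import numpy as np
import pandas as pd
import pysam
import pytest
from hypothesis import given, settings, strategies as st

from symbiospot import phylotyping as pt
from symbiospot import synthetic
from tests.conftest import make_sam


# ---------------------------------------------------------------------------
# barcode mask and demultiplexing


class TestMask:
    def test_round_trip(self, tmp_path):
        mask = {"A" * 25: (0, 0), "C" * 25: (3, 7)}
        path = tmp_path / "mask.tsv"
        pt.write_mask(mask, path)
        assert pt.load_mask(path) == mask

    def test_single_row(self, tmp_path):
        path = tmp_path / "mask.tsv"
        path.write_text("cid\tx\ty\n" + "G" * 25 + "\t5\t6\n")
        assert pt.load_mask(path) == {"G" * 25: (5, 6)}

    def test_duplicate_cid_rejected(self, tmp_path):
        path = tmp_path / "mask.tsv"
        row = "T" * 25 + "\t1\t1\n"
        path.write_text("cid\tx\ty\n" + row + row)
        with pytest.raises(ValueError, match="duplicate"):
            pt.load_mask(path)

    def test_malformed_coordinate_rejected(self, tmp_path):
        path = tmp_path / "mask.tsv"
        path.write_text("cid\tx\ty\n" + "A" * 25 + "\tfoo\t1\n")
        with pytest.raises(ValueError, match="coordinate"):
            pt.load_mask(path)


class TestDemux:
    MASK = {"A" * 25: (2, 3)}

    def test_cid_and_mid_slices(self):
        read1 = "A" * 25 + "CGTACGTACG"
        assert pt.demux(read1, self.MASK) == ((2, 3), "CGTACGTACG")

    def test_unknown_cid_dropped(self):
        assert pt.demux("C" * 25 + "T" * 10, self.MASK) is None

    def test_short_read_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            pt.demux("A" * 34, self.MASK)


# ---------------------------------------------------------------------------
# sequence-mode classification


def brute_force_call(read2: str, refs) -> str:
    """Oracle: scan every offset of both references for a full-window match."""
    for label, win in (("A", refs.window_a), ("G", refs.window_g)):
        for i in range(len(read2) - 46):
            if read2[i:i + 47] == win:
                return label
    return "unclassified"


class TestClassifyRead:
    def test_error_free_fragments(self, refs):
        s, e = refs.window
        frag_g = refs.seq_g[s - 15 : s - 15 + 75]  # covers window fully
        assert pt.classify_read(frag_g, refs) == "G"
        frag_a = refs.seq_a[s - 15 : s - 15 + 75]
        assert pt.classify_read(frag_a, refs) == "A"

    def test_non_diagnostic_window_error_unclassifies(self, refs):
        s, _ = refs.window
        frag = list(refs.seq_a[s - 10 : s - 10 + 75])
        j = 12  # inside the window, away from the diagnostic base
        frag[j] = "A" if frag[j] != "A" else "C"
        assert pt.classify_read("".join(frag), refs) == "unclassified"

    def test_partial_window_coverage_unclassifies(self, refs):
        s, e = refs.window
        # fragment ends one base short of the window end
        frag = refs.seq_a[e - 75 : e - 1]
        assert pt.classify_read(frag, refs) == "unclassified"

    def test_diagnostic_substitution_flips_call(self, refs):
        s, _ = refs.window
        frag = list(refs.seq_a[s - 5 : s - 5 + 75])
        frag[refs.diagnostic_pos - (s - 5) - 1] = "G"
        assert pt.classify_read("".join(frag), refs) == "G"

    def test_agrees_with_brute_force_on_random_reads(self, short_refs):
        rng = np.random.default_rng(42)
        truth = synthetic.TruthTable({(0, 0): 0.5})
        cfg = synthetic.ReadSimConfig(mean_reads_per_spot=500, error_rate=0.02,
                                      seed=21)
        reads = synthetic.simulate_reads(truth, short_refs, cfg)
        for r2 in reads.read2:
            assert pt.classify_read(r2, short_refs) == brute_force_call(r2, short_refs)


# ---------------------------------------------------------------------------
# alignment-mode classification


def _segment(mapq=255, nh=1, cigar="47M", seq=None, ref_start=99, name="r0"):
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "ref_16S", "LN": 200}]}
    )
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.query_sequence = seq
    a.reference_id = 0
    a.reference_start = ref_start
    a.mapping_quality = mapq
    a.cigarstring = cigar
    a.set_tag("NH", nh)
    a.flag = 0
    return a


class TestClassifyAlignment:
    FILTER = pt.AlignmentFilter()

    def test_passing_record_called_by_diagnostic_base(self, short_refs):
        diag0 = short_refs.diagnostic_pos - 1
        seg = _segment(seq=short_refs.window_g, ref_start=short_refs.window[0] - 1)
        assert pt.classify_alignment(seg, self.FILTER, diag0) == "G"
        seg_a = _segment(seq=short_refs.window_a, ref_start=short_refs.window[0] - 1)
        assert pt.classify_alignment(seg_a, self.FILTER, diag0) == "A"

    @pytest.mark.parametrize("kwargs", [
        {"mapq": 60},                 # wrong mapping quality
        {"nh": 2},                    # multi-hit
        {"cigar": "20M1I26M"},        # insertion breaks 47M
        {"cigar": "46M"},             # wrong match length
    ])
    def test_filter_failures_unclassify(self, short_refs, kwargs):
        diag0 = short_refs.diagnostic_pos - 1
        seq = kwargs.pop("seq", short_refs.window_a)
        if kwargs.get("cigar") == "46M":
            seq = seq[:46]
        if kwargs.get("cigar") == "20M1I26M":
            seq = seq[:20] + "T" + seq[20:46]
        seg = _segment(seq=seq, ref_start=short_refs.window[0] - 1, **kwargs)
        assert pt.classify_alignment(seg, self.FILTER, diag0) == "unclassified"

    def test_non_allele_base_unclassifies(self, short_refs):
        diag0 = short_refs.diagnostic_pos - 1
        seq = list(short_refs.window_a)
        seq[diag0 - (short_refs.window[0] - 1)] = "T"
        seg = _segment(seq="".join(seq), ref_start=short_refs.window[0] - 1)
        assert pt.classify_alignment(seg, self.FILTER, diag0) == "unclassified"

    def test_missing_nh_tag_is_an_error(self, short_refs):
        seg = _segment(seq=short_refs.window_a, ref_start=short_refs.window[0] - 1)
        seg.set_tag("NH", None)
        with pytest.raises(ValueError, match="NH"):
            pt.classify_alignment(seg, self.FILTER, short_refs.diagnostic_pos - 1)

    def test_agrees_with_sequence_mode_on_simulated_reads(self, short_refs,
                                                          tmp_path):
        """The two classification paths agree on indel-free reads."""
        truth = synthetic.TruthTable({(0, 0): 0.5, (0, 1): 0.2})
        cfg = synthetic.ReadSimConfig(mean_reads_per_spot=400, error_rate=0.01,
                                      seed=33)
        reads = synthetic.simulate_reads(truth, short_refs, cfg)
        sam_path = tmp_path / "aln.sam"
        make_sam(reads, short_refs, sam_path)
        seq_calls = {n: pt.classify_read(r2, short_refs)
                     for n, r2 in zip(reads.names, reads.read2)}
        diag0 = short_refs.diagnostic_pos - 1
        with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
            for aln in sam:
                aln_call = pt.classify_alignment(aln, self.FILTER, diag0)
                assert aln_call == seq_calls[aln.query_name]


# ---------------------------------------------------------------------------
# accumulation and binning


def cr(x, y, call, mid="ACGTACGTAC"):
    return pt.ClassifiedRead(spot=(x, y), mid=mid, call=call)


class TestAccumulate:
    def test_basic_tally(self):
        stream = [cr(0, 0, "A"), cr(0, 0, "A"), cr(0, 0, "A"), cr(0, 0, "G")]
        counts = pt.accumulate(stream)
        assert counts.counts[(0, 0)]["A"] == 3
        assert counts.counts[(0, 0)]["G"] == 1

    def test_mid_deduplication(self):
        stream = [cr(0, 0, "A", mid="AAAAAAAAAA")] * 3
        assert pt.accumulate(stream, dedup_mid=True).counts[(0, 0)]["A"] == 1
        assert pt.accumulate(stream, dedup_mid=False).counts[(0, 0)]["A"] == 3

    @given(st.lists(st.tuples(st.integers(0, 3), st.integers(0, 3),
                              st.sampled_from(["A", "G", "unclassified"]))))
    @settings(deadline=None, max_examples=50)
    def test_stream_conservation(self, triples):
        stream = [cr(x, y, call) for x, y, call in triples]
        counts = pt.accumulate(stream)
        assert counts.total() == len(stream)


class TestBinAggregate:
    def test_full_bin_with_floor_convention(self):
        counts = pt.SpotCounts()
        for x in range(20):
            for y in range(20):
                counts.add((x, y), "A")
        counts.add((20, 0), "G")
        bins = pt.bin_aggregate(counts, bin_size=20, min_reads=180)
        b00 = bins.set_index(["bx", "by"]).loc[(0, 0)]
        assert b00["n_A"] == 400 and bool(b00["valid"])
        b10 = bins.set_index(["bx", "by"]).loc[(1, 0)]
        assert b10["n_G"] == 1 and not bool(b10["valid"])

    def test_validity_threshold_is_inclusive(self):
        for total, valid in [(179, False), (180, True)]:
            counts = pt.SpotCounts()
            counts.add((0, 0), "A", n=total)
            bins = pt.bin_aggregate(counts)
            assert bool(bins["valid"].iloc[0]) is valid

    @given(st.lists(st.tuples(st.integers(0, 59), st.integers(0, 59),
                              st.sampled_from(["A", "G"])), min_size=1),
           st.sampled_from([1, 7, 20]))
    @settings(deadline=None, max_examples=50)
    def test_bin_totals_conserve_spot_totals(self, triples, bin_size):
        counts = pt.SpotCounts()
        for x, y, call in triples:
            counts.add((x, y), call)
        bins = pt.bin_aggregate(counts, bin_size=bin_size)
        assert bins["total"].sum() == len(triples)
        # every spot maps to the bin the floor convention dictates
        for (x, y), c in counts.counts.items():
            assert ((bins["bx"] == x // bin_size) &
                    (bins["by"] == y // bin_size)).any()


class TestCallBins:
    def _one_bin(self, n_a, n_g, min_reads=0):
        counts = pt.SpotCounts()
        if n_a:
            counts.add((0, 0), "A", n=n_a)
        if n_g:
            counts.add((0, 0), "G", n=n_g)
        bins = pt.bin_aggregate(counts, min_reads=min_reads)
        return pt.call_bins(bins)["call"].iloc[0]

    @pytest.mark.parametrize("n_a,n_g,expected", [
        (100, 100, "mixed"),        # 50:50
        (180, 9, "A-dominant"),     # frac 0.9524, ratio 20
        (19, 1, "mixed"),           # exactly 95%: strictly above required
        (1, 19, "mixed"),
        (9, 180, "G-dominant"),
        (200, 0, "A-dominant"),
    ])
    def test_dominance_boundary(self, n_a, n_g, expected):
        assert self._one_bin(n_a, n_g) == expected

    def test_invalid_bins_not_called(self):
        assert self._one_bin(100, 0, min_reads=180) == "invalid"

    def test_dominance_level_validated(self):
        counts = pt.SpotCounts()
        counts.add((0, 0), "A", n=200)
        bins = pt.bin_aggregate(counts)
        with pytest.raises(ValueError):
            pt.call_bins(bins, dominance=0.4)


# ---------------------------------------------------------------------------
# heterogeneity summaries and sample-level frequencies


def bins_frame(rows):
    """rows: (bx, by, n_A, n_G); all valid, called at 0.95."""
    counts = pt.SpotCounts()
    for bx, by, n_a, n_g in rows:
        if n_a:
            counts.add((bx * 20, by * 20), "A", n=n_a)
        if n_g:
            counts.add((bx * 20, by * 20), "G", n=n_g)
    return pt.call_bins(pt.bin_aggregate(counts, min_reads=0))


class TestSummarize:
    def test_all_pure_a(self):
        s = pt.summarize(bins_frame([(0, 0, 200, 0), (1, 0, 250, 0)]))
        assert s.extreme_fraction == 1.0
        assert s.single_phylotype_fraction_strict == 1.0
        assert s.single_phylotype_fraction_dominance == 1.0
        assert s.neighbor_discordance == 0.0

    def test_two_bin_histogram(self):
        s = pt.summarize(bins_frame([(0, 0, 96, 4), (5, 5, 100, 100)]))
        hist = s.histogram
        assert hist[19] == 1          # 0.96 in [0.95, 1.0]
        assert hist[10] == 1          # 0.50 in [0.50, 0.55)
        assert sum(hist) == s.n_valid_bins == 2
        assert s.extreme_fraction == 0.5

    def test_checkerboard_discordance(self):
        rows = [(bx, by, 200 if (bx + by) % 2 == 0 else 0,
                 0 if (bx + by) % 2 == 0 else 200)
                for bx in range(4) for by in range(4)]
        s = pt.summarize(bins_frame(rows))
        assert s.neighbor_discordance == 1.0

    def test_zero_valid_bins_rejected(self):
        counts = pt.SpotCounts()
        counts.add((0, 0), "A", n=5)
        bins = pt.call_bins(pt.bin_aggregate(counts, min_reads=180))
        with pytest.raises(ValueError, match="valid"):
            pt.summarize(bins)


class TestSampleFrequency:
    @pytest.mark.parametrize("n_a,n_g,expected", [
        (0, 10, 1.0), (50, 50, 0.5), (46, 54, 0.54),
    ])
    def test_fraction(self, n_a, n_g, expected):
        assert pt.sample_frequency(n_a, n_g).frac_g == pytest.approx(expected)

    def test_zero_reads_rejected(self):
        with pytest.raises(ValueError):
            pt.sample_frequency(0, 0)


class TestConcordance:
    def test_identical_and_anticorrelated_vectors(self):
        xs = [0.1, 0.4, 0.9, 0.3]
        assert pt.concordance_r2(zip(xs, xs)) == pytest.approx(1.0)
        ys = [1 - x for x in xs]
        assert pt.concordance_r2(zip(xs, ys)) == pytest.approx(1.0)

    def test_matches_definitional_formula(self):
        pairs = [(0, 0), (0.5, 1), (1, 0.5), (0.2, 0.2), (0.8, 0.8)]
        x = np.array([p[0] for p in pairs])
        y = np.array([p[1] for p in pairs])
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        expected = cov**2 / (x.var() * y.var())
        assert pt.concordance_r2(pairs) == pytest.approx(expected, rel=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            pt.concordance_r2([(0.5, 0.1), (0.5, 0.7), (0.5, 0.3)])
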