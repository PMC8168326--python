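import math

import numpy as np
import pytest

from anchorasm.filters import (
    build_kmer_profile,
    detect_abundance_cutoff,
    filter_short_reads,
    filter_unitigs_by_coverage,
    KmerProfile,
)
from anchorasm.io import PafRecord, SequenceRecord


def reads(*seqs):
    return [SequenceRecord(f"r{i}", s) for i, s in enumerate(seqs)]


class TestKmerProfile:
    def test_single_kmer(self):
        prof = build_kmer_profile(reads("ACGT"), k=4)
        assert prof.histogram == {1: 1}

    def test_duplicate_reads_counted(self):
        prof = build_kmer_profile(reads("AAAA", "AAAA"), k=4)
        assert prof.histogram == {2: 1}

    def test_kmers_with_n_skipped(self):
        prof = build_kmer_profile(reads("ACGNT"), k=3)
        # only ACG is N-free
        assert prof.histogram == {1: 1}

    def test_canonical_collapses_strands(self):
        # AACC and its reverse complement GGTT are one canonical k-mer
        prof = build_kmer_profile(reads("AACC", "GGTT"), k=4)
        assert prof.histogram == {2: 1}

    def test_k_longer_than_reads_warns_empty(self):
        prof = build_kmer_profile(reads("ACG"), k=10)
        assert prof.histogram == {}


class TestAbundanceCutoff:
    def test_documented_histogram(self):
        counts = {}
        spec = {1: 900, 2: 300, 3: 50, 10: 100, 20: 400, 30: 600, 40: 350, 50: 100}
        i = 0
        for abundance, n in spec.items():
            for _ in range(n):
                counts[f"k{i}"] = abundance
                i += 1
        prof = KmerProfile(k=21, counts=counts)
        assert prof.histogram == spec
        # valley at 3, main peak at 30 (600), first abundance with count
        # <= 300 beyond the peak is 50
        assert detect_abundance_cutoff(prof) == 50

    def test_all_unique_no_peak(self):
        prof = KmerProfile(k=21, counts={"a": 1, "b": 1})
        assert detect_abundance_cutoff(prof) == math.inf

    def test_override_wins(self):
        prof = KmerProfile(k=21, counts={"a": 1})
        assert detect_abundance_cutoff(prof, override=120) == 120


class TestFilterShortReads:
    def test_infinite_cutoff_keeps_all(self):
        rs = reads("ACGTA", "TTTTT")
        prof = build_kmer_profile(rs, k=5)
        kept, rep = filter_short_reads(rs, prof, math.inf)
        assert kept == rs
        assert rep["fraction_retained"] == 1.0

    def test_abundant_kmer_removes_read(self):
        rs = reads(*(["AAAAA"] * 10 + ["ACGTC"]))
        prof = build_kmer_profile(rs, k=5)
        kept, rep = filter_short_reads(rs, prof, cutoff=5)
        assert [r.seq for r in kept] == ["ACGTC"]
        assert rep["n_retained"] == 1

    def test_idempotent(self):
        rs = reads("AAAAA", "AAAAA", "ACGTC", "GGGGG")
        prof = build_kmer_profile(rs, k=5)
        once, _ = filter_short_reads(rs, prof, cutoff=1)
        twice, _ = filter_short_reads(once, prof, cutoff=1)
        assert once == twice


def paf(uid, ulen, s0, s1, rid="r0"):
    return PafRecord(uid, ulen, s0, s1, "+", rid, 10000, 0, s1 - s0,
                     max(1, s1 - s0), s1 - s0, 60)


def unitig(uid, length):
    return SequenceRecord(uid, "A" * length)


class TestUnitigCoverageFilter:
    def test_quartile_outlier_detection(self):
        # max coverages [1,2,3,4,100]: Q1=2, Q3=4, threshold 4+3=7
        unitigs = [unitig(f"u{i}", 1000) for i in range(5)]
        recs = []
        for i, depth in enumerate([1, 2, 3, 4, 100]):
            recs += [paf(f"u{i}", 1000, 0, 1000, rid=f"r{j}") for j in range(depth)]
        kept, rep = filter_unitigs_by_coverage(unitigs, recs)
        assert rep["q1"] == 2 and rep["q3"] == 4 and rep["threshold"] == 7
        assert rep["n_flagged"] == 1
        assert {u.id for u in kept} == {"u0", "u1", "u2", "u3"}

    def test_identical_coverage_none_flagged(self):
        unitigs = [unitig(f"u{i}", 800) for i in range(4)]
        recs = [paf(f"u{i}", 800, 0, 800, rid=f"r{j}") for i in range(4) for j in range(5)]
        kept, rep = filter_unitigs_by_coverage(unitigs, recs)
        assert rep["n_flagged"] == 0
        assert len(kept) == 4

    def test_rescue_of_low_coverage_region(self):
        # flagged 2000 bp unitig whose first 600 bp stay at background depth
        unitigs = [unitig(f"u{i}", 1000) for i in range(4)] + [unitig("hot", 2000)]
        recs = [paf(f"u{i}", 1000, 0, 1000, rid=f"r{j}") for i in range(4) for j in range(3)]
        recs += [paf("hot", 2000, 0, 2000, rid=f"ra{j}") for j in range(3)]
        recs += [paf("hot", 2000, 600, 2000, rid=f"rb{j}") for j in range(40)]
        kept, rep = filter_unitigs_by_coverage(unitigs, recs, rescue_min_len=500)
        assert rep["n_flagged"] == 1
        assert rep["n_rescued"] == 1
        frag = [u for u in kept if u.id.startswith("hot:rescue:")]
        assert frag[0].id == "hot:rescue:0-600"
        assert frag[0].length == 600

    def test_rescued_fragments_avoid_high_coverage(self):
        # property: no rescued fragment overlaps a position above Q3
        rng = np.random.default_rng(7)
        unitigs = [unitig(f"u{i}", 1500) for i in range(8)]
        recs = []
        for i in range(8):
            depth = 3 if i < 7 else 1
            recs += [paf(f"u{i}", 1500, 0, 1500, rid=f"r{i}_{j}") for j in range(depth)]
        # unitig u7: spike in the middle only
        recs += [paf("u7", 1500, 700, 900, rid=f"s{j}") for j in range(50)]
        kept, rep = filter_unitigs_by_coverage(unitigs, recs, rescue_min_len=300)
        for u in kept:
            if u.id.startswith("u7:rescue:"):
                a, b = map(int, u.id.rsplit(":", 1)[1].split("-"))
                assert b <= 700 or a >= 900

    def test_empty_mapping_passes_all(self):
        unitigs = [unitig("u0", 600)]
        kept, rep = filter_unitigs_by_coverage(unitigs, [])
        assert kept == unitigs

    def test_unknown_query_rejected(self):
        with pytest.raises(ValueError, match="not in unitig set"):
            filter_unitigs_by_coverage([unitig("u0", 600)], [paf("zz", 600, 0, 600)])

    def test_perfect_uniform_data_unchanged(self):
        # no repeats, even coverage: the output set equals the input set
        unitigs = [unitig(f"u{i}", 1000) for i in range(20)]
        recs = [
            paf(f"u{i}", 1000, 0, 1000, rid=f"r{i}_{j}")
            for i in range(20)
            for j in range(10)
        ]
        kept, rep = filter_unitigs_by_coverage(unitigs, recs)
        assert kept == unitigs
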