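import numpy as np
import pytest

from anchorasm.graph import (
    CONTAINED_R1,
    CONTAINED_R2,
    DIR_BACKWARD,
    DIR_FORWARD,
    MatchPair,
    build_overlap_graph,
    chain_matches,
    classify_edge,
    flag_chimeric_reads,
    pair_score,
    project_s_interval,
    significant_matches,
    tau,
)
from anchorasm.io import PafRecord
from conftest import oracle_chain, random_chain_instance, sm


def paf(uid, rid, n_matches, strand="+", s=(0, 900), r=(100, 1000),
        ulen=1000, rlen=8000):
    return PafRecord(uid, ulen, s[0], s[1], strand, rid, rlen, r[0], r[1],
                     n_matches, max(s[1] - s[0], r[1] - r[0]), 60)


class TestSignificantMatches:
    def test_at_threshold_kept(self):
        assert len(significant_matches([paf("u", "r", 500)])) == 1

    def test_below_threshold_dropped(self):
        assert significant_matches([paf("u", "r", 499)]) == []

    def test_minus_strand_orientation(self):
        (m,) = significant_matches([paf("u", "r", 600, strand="-")])
        assert m.orientation == -1

    def test_split_mappings_merged_by_score(self):
        ms = significant_matches(
            [paf("u", "r", 600, s=(0, 700), r=(0, 700)),
             paf("u", "r", 800, s=(0, 900), r=(0, 900))]
        )
        assert len(ms) == 1 and ms[0].delta == 800


class TestTau:
    # match [11,20] on the unitig -> [101,120] on the read (ratio 2)
    M = (11, 20, 101, 120)

    def test_endpoints_map_to_endpoints(self):
        assert tau(*self.M, 11) == 101
        assert tau(*self.M, 20) == 120

    def test_interpolation_far_from_right_end(self):
        assert tau(*self.M, 15) == 109

    def test_interpolation_near_right_end(self):
        assert tau(*self.M, 16) == 112

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            tau(*self.M, 21)

    def test_monotone_over_interval(self):
        vals = [tau(*self.M, h) for h in range(11, 21)]
        assert vals == sorted(vals)

    def test_monotone_random_matches(self, rng):
        # the two interpolation branches meet mid-interval; when the read
        # interval is the shorter one they disagree by < 1 bp there, so
        # monotonicity holds up to a single-bp seam step
        for _ in range(200):
            i = int(rng.integers(0, 1000))
            j = i + int(rng.integers(1, 2000))
            ip = int(rng.integers(0, 8000))
            jp = ip + int(rng.integers(1, 3000))
            vals = [tau(i, j, ip, jp, h) for h in range(i, j + 1, max(1, (j - i) // 17))]
            assert all(b >= a - 1 for a, b in zip(vals, vals[1:]))
            assert tau(i, j, ip, jp, i) == ip and tau(i, j, ip, jp, j) == jp


class TestProjectSInterval:
    def test_forward_projection(self):
        m = sm("u", "r", (10, 21), (100, 122))
        assert project_s_interval(m, 10, 21) == (100, 122)

    def test_reverse_projection_mirrors(self):
        m = sm("u", "r", (0, 100), (500, 600), orientation=-1)
        # unitig start maps to the read-interval end under reverse matches
        a, b = project_s_interval(m, 0, 10)
        assert (a, b) == (590, 600)


class TestPairScore:
    def test_partial_overlap(self):
        m1 = sm("u", "r1", (0, 100), (0, 100), delta=90)   # paper [1,100]
        m2 = sm("u", "r2", (50, 150), (0, 100), delta=80)  # paper [51,150]
        assert pair_score(m1, m2) == pytest.approx(42.5)

    def test_disjoint_is_zero(self):
        m1 = sm("u", "r1", (0, 50), (0, 50), delta=50)
        m2 = sm("u", "r2", (59, 100), (0, 41), delta=41)
        assert pair_score(m1, m2) == 0.0

    def test_perfect_match_limit(self):
        m1 = sm("u", "r1", (0, 200), (0, 200), delta=200)
        m2 = sm("u", "r2", (0, 200), (0, 200), delta=200)
        assert pair_score(m1, m2) == pytest.approx(200.0)

    def test_symmetric_and_nonnegative(self, rng):
        for _ in range(100):
            a = sorted(rng.integers(0, 500, size=2))
            b = sorted(rng.integers(0, 500, size=2))
            if a[0] == a[1] or b[0] == b[1]:
                continue
            m1 = sm("u", "r1", (a[0], a[1]), (0, a[1] - a[0]), delta=a[1] - a[0])
            m2 = sm("u", "r2", (b[0], b[1]), (0, b[1] - b[0]), delta=b[1] - b[0])
            assert pair_score(m1, m2) == pair_score(m2, m1) >= 0
            disjoint = m1.s_end <= m2.s_start or m2.s_end <= m1.s_start
            assert (pair_score(m1, m2) == 0) == disjoint


def pair_at(uid, r1_pos, r2_pos, theta1=+1, theta2=+1, length=100):
    m1 = sm(uid, "r1", (0, length), (r1_pos, r1_pos + length), theta1, delta=length)
    m2 = sm(uid, "r2", (0, length), (r2_pos, r2_pos + length), theta2, delta=length)
    return MatchPair(m1, m2)


class TestChaining:
    def test_colinear_pair_fully_chained(self):
        p1 = pair_at("u1", 100, 100)
        p2 = pair_at("u2", 300, 300)
        chain, score, theta = chain_matches([p1, p2])
        assert [p.unitig_id for p in chain] == ["u1", "u2"]
        assert score == pytest.approx(p1.omega + p2.omega)
        assert theta == +1

    def test_opposite_signatures_split(self):
        p1 = pair_at("u1", 100, 100, theta1=+1)
        p2 = pair_at("u2", 300, 300, theta1=-1, length=150)
        chain, score, theta = chain_matches([p1, p2])
        assert [p.unitig_id for p in chain] == ["u2"]  # larger omega wins
        assert theta == -1

    def test_order_conflict_keeps_one(self):
        p1 = pair_at("u1", 100, 300)
        p2 = pair_at("u2", 300, 100)
        chain, score, _ = chain_matches([p1, p2])
        assert len(chain) == 1

    def test_reverse_strand_chain(self):
        # same unitig order on r1, mirrored on r2: consistent for theta=-1
        p1 = pair_at("u1", 100, 900, theta2=-1)
        p2 = pair_at("u2", 500, 500, theta2=-1)
        chain, _, theta = chain_matches([p1, p2])
        assert len(chain) == 2 and theta == -1

    def test_gap_tolerance_breaks_chain(self):
        p1 = pair_at("u1", 0, 0)
        p2 = pair_at("u2", 500, 3000)  # distances 500 vs 3000
        chain, _, _ = chain_matches([p1, p2])
        assert len(chain) == 1

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(500):
            pairs = random_chain_instance(rng, max_unitigs=10)
            chain, score, _ = chain_matches(pairs)
            oscore, ochain = oracle_chain(pairs)
            assert score == pytest.approx(oscore)
            assert [p.unitig_id for p in chain] == [p.unitig_id for p in ochain]


class TestClassifyEdge:
    def two_read_edge(self, span1, span2, len1, len2, sig=+1):
        m1 = sm("u", "r1", (0, span1[1] - span1[0]), span1, delta=span1[1] - span1[0])
        m2 = sm("u", "r2", (0, span2[1] - span2[0]), span2, delta=span2[1] - span2[0])
        pair = MatchPair(m1, m2)
        return classify_edge("r1", "r2", [pair], 1000.0, sig, len1, len2)

    def test_left_extension_only(self):
        # r1 overhang left 500 > 100; right 50 < 400
        e = self.two_read_edge((500, 950), (100, 550), len1=1000, len2=950)
        assert e.direction == DIR_FORWARD

    def test_contained_read(self):
        e = self.two_read_edge((50, 940), (400, 1290), len1=1000, len2=1590)
        assert e.direction == CONTAINED_R1

    def test_containment_of_partner(self):
        # r1 extends on both sides: r2 is nested
        e = self.two_read_edge((500, 900), (100, 500), len1=2000, len2=600)
        assert e.direction == CONTAINED_R2

    def test_reverse_strand_extension(self):
        # theta=-1: r2's overhangs are read from its other end
        e = self.two_read_edge((500, 900), (100, 500), len1=1000, len2=550, sig=-1)
        # left: 500 > 550-500=50; right: 100 > 100? no (not strict)
        assert e.direction == DIR_FORWARD


def chained_reads_matches(n_reads=6, read_len=8000, step=2000, unitig_len=1000):
    """Perfect tiling of reads over a linear genome, anchors every 2 kb."""
    matches = []
    lengths = {}
    genome_len = step * (n_reads - 1) + read_len
    for i in range(n_reads):
        rid = f"r{i:02d}"
        lengths[rid] = read_len
        start = i * step
        for k in range(genome_len // step):
            u0 = k * step + 500
            lo, hi = max(start, u0), min(start + read_len, u0 + unitig_len)
            if hi - lo >= 500:
                matches.append(
                    sm(f"u{k:02d}", rid, (lo - u0, hi - u0), (lo - start, hi - start),
                       delta=hi - lo)
                )
    return matches, lengths


class TestBuildOverlapGraph:
    def test_perfect_tiling_connected(self):
        matches, lengths = chained_reads_matches()
        g = build_overlap_graph(matches, lengths)
        assert g.n_components() == 1
        assert g.vertices == set(lengths)

    def test_no_shared_unitig_no_edge(self):
        ms = [sm("u1", "r1", (0, 600), (0, 600)), sm("u2", "r2", (0, 600), (0, 600))]
        g = build_overlap_graph(ms, {"r1": 1000, "r2": 1000})
        assert g.edges == {}

    def test_contained_read_contracted(self):
        # r2 nested inside r1; r3 overlaps r1 to the right
        ms = [
            sm("uA", "r1", (0, 1000), (2000, 3000), delta=1000),
            sm("uA", "r2", (0, 1000), (500, 1500), delta=1000),
            sm("uB", "r1", (0, 1000), (7000, 8000), delta=1000),
            sm("uB", "r3", (0, 1000), (500, 1500), delta=1000),
        ]
        g = build_overlap_graph(ms, {"r1": 9000, "r2": 2500, "r3": 8000})
        assert g.vertices == {"r1", "r3"}
        assert g.contained["r2"][0] == "r1"
        assert g.edge("r1", "r3") is not None

    def test_no_vertex_contained_in_neighbor_after_contraction(self):
        matches, lengths = chained_reads_matches(n_reads=8)
        # add a short read nested in the middle
        matches.append(sm("u03", "nest", (0, 1000), (100, 1100), delta=1000))
        lengths["nest"] = 1500
        g = build_overlap_graph(matches, lengths)
        assert "nest" not in g.vertices
        for e in g.iter_edges():
            assert e.direction in (DIR_FORWARD, DIR_BACKWARD)


class TestChimeraFlagging:
    def test_perfect_tiling_unflagged(self):
        matches, lengths = chained_reads_matches()
        assert flag_chimeric_reads(matches, lengths) == set()

    def test_split_neighborhood_with_contradiction_flagged(self):
        # chimera joins two loci; its two neighbor groups occupy disjoint
        # parts of it, and each neighbor extends past the junction with
        # anchors the chimera lacks
        matches, lengths = [], {}
        # locus A reads share uA1 with the chimera's left half; they also
        # carry uA2 just beyond the junction
        chim = "chim"
        lengths[chim] = 8000
        matches.append(sm("uA1", chim, (0, 1000), (2500, 3500), delta=1000))
        matches.append(sm("uB1", chim, (0, 1000), (4500, 5500), delta=1000))
        for i, rid in enumerate(("a1", "a2")):
            lengths[rid] = 8000
            matches.append(sm("uA1", rid, (0, 1000), (2500, 3500), delta=1000))
            matches.append(sm("uA2", rid, (0, 1000), (4500, 5500), delta=1000))
        for rid in ("b1", "b2"):
            lengths[rid] = 8000
            matches.append(sm("uB1", rid, (0, 1000), (4500, 5500), delta=1000))
            matches.append(sm("uB2", rid, (0, 1000), (2500, 3500), delta=1000))
        assert flag_chimeric_reads(matches, lengths) == {"chim"}
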