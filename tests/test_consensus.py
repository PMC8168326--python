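import numpy as np
import pytest

from anchorasm._util import revcomp
from anchorasm.consensus import (
    assign_run_indices,
    build_layout,
    cluster_occurrences,
    consensus_for_path,
    path_edge_occurrences,
    project_sequence,
)
from anchorasm.graph import MatchPair, OverlapEdge, DIR_FORWARD
from anchorasm.paths import ContigPath
from conftest import sm


def edge_with(r1, r2, pairs, sig=+1):
    chain = tuple(pairs)
    a1 = min(p.m1.r_start for p in chain)
    b1 = max(p.m1.r_end for p in chain)
    a2 = min(p.m2.r_start for p in chain)
    b2 = max(p.m2.r_end for p in chain)
    return OverlapEdge(r1=r1, r2=r2, signature=sig, score=1000.0, chain=chain,
                       span_r1=(a1, b1), span_r2=(a2, b2), direction=DIR_FORWARD)


def occ(path):
    return path_edge_occurrences(path)


def simple_path(edge_unitigs):
    """Path r0 -> r1 -> ... with the given unitig ids on each edge.

    Unitig k sits at position 1000*k+... on a virtual genome; reads step by
    2000 bp and are 6000 bp long.
    """
    n = len(edge_unitigs) + 1
    step, rlen = 2000, 6000
    upos = {}
    arcs = []
    for i, unitigs in enumerate(edge_unitigs):
        r1, r2 = f"r{i}", f"r{i+1}"
        pairs = []
        for u in unitigs:
            g = upos.setdefault(u, 2000 + 1500 * len(upos))
            pairs.append(
                MatchPair(
                    sm(u, r1, (0, 1000), (g - i * step, g - i * step + 1000), delta=1000),
                    sm(u, r2, (0, 1000), (g - (i + 1) * step, g - (i + 1) * step + 1000),
                       delta=1000),
                )
            )
        arcs.append(edge_with(r1, r2, pairs))
    return ContigPath(vertices=tuple(f"r{i}" for i in range(n)), kind="primary", arcs=arcs)


class TestClustering:
    def make_path_with_intervals(self, intervals):
        """Three-edge path where unitig 'u' appears on each edge with the
        given s-intervals (None = absent)."""
        arcs = []
        for i, iv in enumerate(intervals):
            r1, r2 = f"r{i}", f"r{i+1}"
            pairs = [
                MatchPair(
                    sm("anchor", r1, (0, 600), (3000, 3600), delta=600),
                    sm("anchor", r2, (0, 600), (1000, 1600), delta=600),
                )
            ]
            if iv is not None:
                pairs.append(
                    MatchPair(
                        sm("u", r1, iv, (4000, 4000 + iv[1] - iv[0]), delta=iv[1] - iv[0]),
                        sm("u", r2, iv, (2000, 2000 + iv[1] - iv[0]), delta=iv[1] - iv[0]),
                    )
                )
            arcs.append(edge_with(r1, r2, pairs))
        return ContigPath(
            vertices=tuple(f"r{i}" for i in range(len(intervals) + 1)),
            kind="primary", arcs=arcs,
        )

    def test_overlapping_intervals_one_clique(self):
        path = self.make_path_with_intervals([(100, 400), (150, 450)])
        c = cluster_occurrences(occ(path))
        assert c[("u", 0)] == c[("u", 1)]

    def test_disjoint_intervals_two_cliques(self):
        path = self.make_path_with_intervals([(100, 400), (500, 800)])
        c = cluster_occurrences(occ(path))
        assert c[("u", 0)] != c[("u", 1)]

    def test_chained_overlap_greedy_two_cliques(self):
        # e0-e1 overlap and e1-e2 overlap, but e0-e2 do not
        path = self.make_path_with_intervals([(100, 400), (300, 600), (500, 800)])
        c = cluster_occurrences(occ(path))
        assert c[("u", 0)] == c[("u", 1)] != c[("u", 2)]

    def test_run_indices_contiguous(self):
        path = self.make_path_with_intervals([(100, 400), (100, 400), (100, 400)])
        g = assign_run_indices(occ(path))
        assert g[("u", 0)] == g[("u", 1)] == g[("u", 2)]

    def test_run_split_by_absent_edge(self):
        path = self.make_path_with_intervals([(100, 400), None, (100, 400)])
        g = assign_run_indices(occ(path))
        assert g[("u", 0)] != g[("u", 2)]

    def test_single_node_path_no_indices(self):
        path = ContigPath(vertices=("r0",), kind="singleton", arcs=[])
        assert cluster_occurrences(occ(path)) == {}
        assert assign_run_indices(occ(path)) == {}


class TestLayoutAndProjection:
    def test_coordinates_follow_genomic_spacing(self):
        path = simple_path([["u0", "u1"], ["u1", "u2"]])
        phi = {v: +1 for v in path.vertices}
        layout = build_layout(path, phi, {v: 6000 for v in path.vertices})
        coords = {k[0]: v for k, v in layout.coordinates.items()}
        assert coords["u1"][0] - coords["u0"][0] == 1500
        assert coords["u2"][0] - coords["u1"][0] == 1500

    def test_projection_reconstructs_genome(self):
        rng = np.random.default_rng(0)
        genome = "".join(rng.choice(list("ACGT"), size=12000))
        step, rlen = 2000, 6000
        reads = {f"r{i}": genome[i * step : i * step + rlen] for i in range(4)}
        upos = {"u0": 2500, "u1": 4500, "u2": 6500}
        unitigs = {u: genome[p : p + 1000] for u, p in upos.items()}
        arcs = []
        for i in range(3):
            r1, r2 = f"r{i}", f"r{i+1}"
            pairs = []
            for u, g in upos.items():
                if g >= i * step and g + 1000 <= i * step + rlen and \
                   g >= (i + 1) * step and g + 1000 <= (i + 1) * step + rlen:
                    pairs.append(
                        MatchPair(
                            sm(u, r1, (0, 1000), (g - i * step, g - i * step + 1000),
                               delta=1000),
                            sm(u, r2, (0, 1000),
                               (g - (i + 1) * step, g - (i + 1) * step + 1000),
                               delta=1000),
                        )
                    )
            arcs.append(edge_with(r1, r2, pairs))
        path = ContigPath(vertices=("r0", "r1", "r2", "r3"), kind="primary", arcs=arcs)
        phi = {v: +1 for v in path.vertices}
        seq, placements = consensus_for_path(path, phi, unitigs, reads)
        assert seq == genome[: 3 * step + rlen]
        # placement table tiles the contig exactly
        placements.sort(key=lambda row: row[2])
        assert placements[0][2] == 0 and placements[-1][3] == len(seq)
        for a, b in zip(placements, placements[1:]):
            assert a[3] == b[2]

    def test_single_node_path_is_oriented_read(self):
        reads = {"r0": "ACGTACGT"}
        seq, placements = consensus_for_path(
            ContigPath(vertices=("r0",), kind="singleton", arcs=[]),
            {"r0": -1}, {}, reads,
        )
        assert seq == revcomp("ACGTACGT")
        assert placements == [("r0", "long-read", 0, 8, "-")]
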