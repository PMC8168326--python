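"""Shared builders and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from anchorasm.dag import DirectedOverlapGraph
from anchorasm.graph import (
    DIR_BACKWARD,
    DIR_FORWARD,
    MatchPair,
    OverlapEdge,
    OverlapGraph,
    SignificantMatch,
)


def sm(unitig, read, s, r, orientation=+1, delta=None):
    """Terse SignificantMatch builder; intervals are (start, end) tuples."""
    if delta is None:
        delta = min(s[1] - s[0], r[1] - r[0])
    return SignificantMatch(
        unitig_id=unitig,
        read_id=read,
        s_start=s[0],
        s_end=s[1],
        r_start=r[0],
        r_end=r[1],
        orientation=orientation,
        delta=delta,
    )


def toy_edge(u, v, signature=+1, score=1000.0, direction=DIR_FORWARD,
             span1=(0, 100), span2=(0, 100), chain=()):
    return OverlapEdge(
        r1=u, r2=v, signature=signature, score=score, chain=tuple(chain),
        span_r1=span1, span_r2=span2, direction=direction,
    )


def toy_graph(edges, lengths=None):
    """OverlapGraph from (u, v, signature, score) tuples."""
    g = OverlapGraph()
    for (u, v, sig, score) in edges:
        a, b = (u, v) if u < v else (v, u)
        g.vertices.update((a, b))
        g.edges[(a, b)] = toy_edge(a, b, signature=sig, score=score)
    if lengths is None:
        lengths = {v: 1000 for v in g.vertices}
    g.read_lengths = lengths
    return g


def toy_digraph(arcs):
    """DirectedOverlapGraph from (u, v, weight) or (u, v) tuples."""
    d = DirectedOverlapGraph()
    for arc in arcs:
        u, v, *w = arc
        d.vertices.update((u, v))
        d.arcs[(u, v)] = float(w[0]) if w else 1.0
    return d


# ---------------------------------------------------------------------------
# random instance generators


def random_signed_graph(rng, max_n=12, p=0.4):
    n = int(rng.integers(2, max_n + 1))
    edges = []
    for u, v in itertools.combinations(range(n), 2):
        if rng.random() < p:
            sig = +1 if rng.random() < 0.5 else -1
            edges.append((f"v{u:02d}", f"v{v:02d}", sig, float(rng.random() * 100 + 1)))
    g = toy_graph(edges)
    for i in range(n):
        g.vertices.add(f"v{i:02d}")
        g.read_lengths.setdefault(f"v{i:02d}", 1000)
    return g


def random_digraph(rng, max_n=10, p=0.35, acyclic=False):
    n = int(rng.integers(2, max_n + 1))
    arcs = []
    order = rng.permutation(n)
    for i, j in itertools.permutations(range(n), 2):
        if acyclic and list(order).index(i) > list(order).index(j):
            continue
        if rng.random() < p:
            arcs.append((f"v{i:02d}", f"v{j:02d}", float(rng.random() * 100 + 1)))
    d = toy_digraph(arcs)
    for i in range(n):
        d.vertices.add(f"v{i:02d}")
    return d


def random_chain_instance(rng, max_unitigs=10):
    """Anchors of up to ``max_unitigs`` unitigs shared by two reads."""
    n = int(rng.integers(1, max_unitigs + 1))
    pairs = []
    for k in range(n):
        s_len = int(rng.integers(500, 1500))
        a1 = int(rng.integers(0, s_len - 400))
        b1 = int(rng.integers(a1 + 300, s_len + 1))
        a2 = int(rng.integers(0, s_len - 400))
        b2 = int(rng.integers(a2 + 300, s_len + 1))
        r1 = int(rng.integers(0, 8000))
        r2 = int(rng.integers(0, 8000))
        o1 = +1 if rng.random() < 0.5 else -1
        o2 = +1 if rng.random() < 0.5 else -1
        m1 = sm(f"u{k:02d}", "r1", (a1, b1), (r1, r1 + (b1 - a1)), o1,
                delta=int((b1 - a1) * 0.9))
        m2 = sm(f"u{k:02d}", "r2", (a2, b2), (r2, r2 + (b2 - a2)), o2,
                delta=int((b2 - a2) * 0.9))
        pairs.append(MatchPair(m1, m2))
    return pairs


# ---------------------------------------------------------------------------
# independent oracles


def oracle_chain(pairs, gap_abs=400, gap_frac=0.3):
    """Exhaustive-enumeration optimum of the chaining problem.

    Mirrors the problem definition: pairwise equal signature and order
    consistency, gap tolerance between consecutive anchors, maximal summed
    pair score; ties prefer the earlier leftmost anchor on r1, then the
    lexicographically smaller unitig sequence.
    """
    from anchorasm.graph import _pairs_consistent

    def sort_key(p):
        return (p.m1.r_start, p.m1.r_end, p.unitig_id)

    best = None
    for size in range(1, len(pairs) + 1):
        for combo in itertools.combinations(sorted(pairs, key=sort_key), size):
            ok = all(
                _pairs_consistent(combo[i], combo[i + 1], gap_abs, gap_frac)
                for i in range(len(combo) - 1)
            )
            if not ok:
                continue
            score = sum(p.omega for p in combo)
            key = (-score, combo[0].m1.r_start, tuple(p.unitig_id for p in combo))
            if best is None or key < best[0]:
                best = (key, score, combo)
    return best[1], list(best[2])


def all_cycles_positive(graph: OverlapGraph) -> bool:
    """Exhaustively enumerate every simple cycle and check its signature."""
    import networkx as nx

    g = graph.to_networkx()
    for cycle in nx.simple_cycles(g):
        prod = 1
        cyc = list(cycle) + [cycle[0]]
        for u, v in zip(cyc, cyc[1:]):
            prod *= graph.edge(u, v).signature
        if prod != 1:
            return False
    return True


def min_feedback_arc_set_size(d: DirectedOverlapGraph) -> int:
    """Exact minimum feedback arc set by DP over vertex subsets."""
    verts = sorted(d.vertices)
    idx = {v: i for i, v in enumerate(verts)}
    n = len(verts)
    in_arcs = [[] for _ in range(n)]
    for (u, v) in d.arcs:
        in_arcs[idx[v]].append(idx[u])
    INF = float("inf")
    f = [INF] * (1 << n)
    f[0] = 0
    for mask in range(1 << n):
        if f[mask] == INF:
            continue
        for v in range(n):
            if mask & (1 << v):
                continue
            back = sum(1 for u in in_arcs[v] if not (mask & (1 << u)) and u != v)
            nxt = mask | (1 << v)
            cost = f[mask] + back
            if cost < f[nxt]:
                f[nxt] = cost
    return int(f[(1 << n) - 1])


def longest_path_nodes(arcs, vertices) -> int:
    """Number of nodes on a longest path of a DAG (networkx oracle)."""
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(vertices)
    g.add_edges_from(arcs)
    return len(nx.dag_longest_path(g)) if vertices else 0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
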