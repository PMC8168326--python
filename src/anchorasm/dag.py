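"""Reduction of the oriented overlap graph to a DAG.

Edges are directed by combining each overlap's local direction of extension
with the vertex orientation phi, so that arcs point from a read towards reads
it extends to the left of (i.e. towards larger assembly coordinates).  Any
remaining cycles — spurious back-links from unrecognised repeats — are broken
by a modified Kahn topological sort: when no true source exists, an "almost
source" is chosen among the unsorted out-neighbors K of the sorted set W, and
its in-arcs from outside W become feedback arcs.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

from networkx.utils import UnionFind

from .graph import DIR_BACKWARD, DIR_FORWARD, OverlapEdge, OverlapGraph


@dataclass
class DirectedOverlapGraph:
    vertices: set[str] = field(default_factory=set)
    arcs: dict[tuple[str, str], float] = field(default_factory=dict)
    edge_payload: dict[tuple[str, str], OverlapEdge] = field(default_factory=dict)
    topo_order: list[str] = field(default_factory=list)
    feedback_set: set[tuple[str, str]] = field(default_factory=set)

    def out_neighbors(self, u: str) -> list[str]:
        return [v for (x, v) in self.arcs if x == u]

    def in_neighbors(self, u: str) -> list[str]:
        return [x for (x, v) in self.arcs if v == u]

    def without_feedback(self) -> "DirectedOverlapGraph":
        arcs = {a: w for a, w in self.arcs.items() if a not in self.feedback_set}
        return DirectedOverlapGraph(
            vertices=set(self.vertices),
            arcs=arcs,
            edge_payload={a: e for a, e in self.edge_payload.items() if a in arcs},
            topo_order=list(self.topo_order),
        )

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.vertices)
        for (u, v), w in self.arcs.items():
            g.add_edge(u, v, weight=w)
        return g


def orient_arcs(graph: OverlapGraph, phi: dict[str, int]) -> DirectedOverlapGraph:
    """Direct every overlap edge using phi and the local extension direction.

    The arc runs r1 -> r2 when phi(r1) = +1 and r1 extends the overlap to the
    left (or phi(r1) = -1 and r2 does), and r2 -> r1 otherwise.
    """
    d = DirectedOverlapGraph(vertices=set(graph.vertices))
    for (r1, r2), edge in graph.edges.items():
        if edge.direction == DIR_FORWARD:
            forward = phi[r1] == +1
        elif edge.direction == DIR_BACKWARD:
            forward = phi[r1] == -1
        else:  # containments must have been contracted already
            raise ValueError(f"edge {r1}-{r2} still marked as containment")
        arc = (r1, r2) if forward else (r2, r1)
        d.arcs[arc] = edge.score
        d.edge_payload[arc] = edge
    return d


def modified_kahn(d: DirectedOverlapGraph) -> tuple[list[str], set[tuple[str, str]]]:
    """Topological sort with feedback-arc emission.

    True sources are dequeued preferring the largest total Omega-weight of
    in-arcs from the sorted prefix W (priority queue; ties by vertex id).
    When no source exists, candidates are the unsorted out-neighbors K of W:
    (1) if some candidate has no in-arc from another candidate, pick among
    those the one with the largest weight from W; (2) otherwise pick the
    candidate maximising (weight from W) - (weight from K).  The chosen
    vertex's in-arcs from outside W are appended to the feedback set F.
    If K is empty while vertices remain (an unreached cyclic component), the
    rules are applied to all unsorted vertices.

    Returns ``(W, F)``; the graph minus F is acyclic and W is one of its
    topological orders.
    """
    out_adj: dict[str, list[tuple[str, float]]] = {v: [] for v in d.vertices}
    in_adj: dict[str, list[tuple[str, float]]] = {v: [] for v in d.vertices}
    for (u, v), w in d.arcs.items():
        out_adj[u].append((v, w))
        in_adj[v].append((u, w))

    unsorted = set(d.vertices)
    in_w = dict.fromkeys(d.vertices, 0.0)  # Omega-weight incoming from W
    arcs_from_w = dict.fromkeys(d.vertices, 0)
    in_rem = {v: len(in_adj[v]) for v in d.vertices}
    order: list[str] = []
    feedback: set[tuple[str, str]] = set()
    heap: list[tuple[float, str]] = []
    for v in d.vertices:
        if in_rem[v] == 0:
            heapq.heappush(heap, (-in_w[v], v))

    def pop_source() -> str | None:
        while heap:
            negw, v = heap[0]
            if v not in unsorted or in_rem[v] != 0 or -negw != in_w[v]:
                heapq.heappop(heap)
                continue
            heapq.heappop(heap)
            return v
        return None

    while unsorted:
        u = pop_source()
        if u is None:
            k = {v for v in unsorted if arcs_from_w[v] > 0}
            if not k:
                # W has no unsorted out-neighbor (start of a cyclic
                # component): the sort must enter through a source strongly
                # connected component of the unsorted subgraph, whose
                # members' unsorted in-arcs all stay inside it
                import networkx as nx

                sub = nx.DiGraph()
                sub.add_nodes_from(unsorted)
                sub.add_edges_from(
                    a for a in d.arcs if a[0] in unsorted and a[1] in unsorted
                )
                cond = nx.condensation(sub)
                k = set()
                for node in cond.nodes:
                    if cond.in_degree(node) == 0:
                        k |= cond.nodes[node]["members"]
            case1 = [v for v in k if not any(x in k and x != v for x, _ in in_adj[v])]
            if case1:
                u = max(case1, key=lambda v: (in_w[v], _RevStr(v)))
            else:
                def balance(v: str) -> float:
                    from_k = sum(w for x, w in in_adj[v] if x in k and x != v)
                    return in_w[v] - from_k

                u = max(k, key=lambda v: (balance(v), _RevStr(v)))
            for x, _ in in_adj[u]:
                if x in unsorted:
                    feedback.add((x, u))
        unsorted.discard(u)
        order.append(u)
        for v, w in out_adj[u]:
            if v not in unsorted:
                continue
            in_w[v] += w
            arcs_from_w[v] += 1
            in_rem[v] -= 1
            if in_rem[v] == 0:
                heapq.heappush(heap, (-in_w[v], v))
    return order, feedback


class _RevStr(str):
    """max() with this key prefers the lexicographically smaller id on ties."""

    def __lt__(self, other):
        return str.__gt__(self, other)


def repair_spanning_forest(
    graph: OverlapGraph,
    forest: set[tuple[str, str]],
    feedback: set[tuple[str, str]],
) -> tuple[set[tuple[str, str]], bool]:
    """Re-establish an Omega-maximal spanning forest after feedback removal.

    Feedback arcs correspond to undirected edges that leave the graph.  If
    none of them is a forest edge the forest is unchanged; otherwise Kruskal
    is simply re-run on the surviving edges.  Returns ``(forest, changed)``.
    """
    dropped = {(u, v) if u < v else (v, u) for (u, v) in feedback}
    if not (dropped & forest):
        return forest, False
    uf = UnionFind(graph.vertices)
    new_forest: set[tuple[str, str]] = set()
    for key, edge in sorted(graph.edges.items(), key=lambda kv: (-kv[1].score, kv[0])):
        if key in dropped:
            continue
        u, v = key
        if uf[u] != uf[v]:
            uf.union(u, v)
            new_forest.add(key)
    return new_forest, True


def remove_feedback(graph: OverlapGraph, feedback: set[tuple[str, str]]) -> OverlapGraph:
    """Undirected view of the graph with the feedback edges deleted."""
    dropped = {(u, v) if u < v else (v, u) for (u, v) in feedback}
    out = OverlapGraph(
        vertices=set(graph.vertices),
        read_lengths=dict(graph.read_lengths),
        contained=dict(graph.contained),
        edges={k: e for k, e in graph.edges.items() if k not in dropped},
    )
    return out
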