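"""Consistent orientation of long reads on the signed overlap graph.

A signed graph is orientable iff every cycle has positive signature product;
it then admits a vertex orientation phi with phi(u)*phi(v) = theta(uv) on
every edge.  The extraction heuristic: (1) build an Omega-maximal spanning
forest (Kruskal), (2) assign phi by multiplying signatures along tree paths
from a per-component reference read, (3) delete every non-tree edge whose
endpoints violate phi(u)*phi(v) = theta(uv).  Because a non-tree edge is
always the Omega-minimum edge of its fundamental cycle, deletions never touch
the forest, so connectivity and the forest's maximality are preserved.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

from networkx.utils import UnionFind

from .graph import OverlapGraph


@dataclass
class OrientationResult:
    forest: set[tuple[str, str]]
    phi: dict[str, int]
    removed_edges: set[tuple[str, str]]
    roots: dict[str, str] = field(default_factory=dict)  # component root per vertex


def max_weight_spanning_forest(graph: OverlapGraph) -> set[tuple[str, str]]:
    """Omega-maximal spanning forest via Kruskal; ties by lexicographic edge key."""
    uf = UnionFind(graph.vertices)
    forest: set[tuple[str, str]] = set()
    for key, edge in sorted(graph.edges.items(), key=lambda kv: (-kv[1].score, kv[0])):
        u, v = key
        if uf[u] != uf[v]:
            uf.union(u, v)
            forest.add(key)
    return forest


def assign_phi(
    graph: OverlapGraph, forest: set[tuple[str, str]]
) -> tuple[dict[str, int], dict[str, str]]:
    """Orient every read by one tree traversal per component.

    The reference read of a component (the longest, ties by id) gets
    phi = +1; every other read gets the product of edge signatures along its
    unique tree path from the reference.
    """
    adj: dict[str, list[str]] = {v: [] for v in graph.vertices}
    for (u, v) in forest:
        adj[u].append(v)
        adj[v].append(u)
    phi: dict[str, int] = {}
    roots: dict[str, str] = {}
    unvisited = set(graph.vertices)
    while unvisited:
        component = _component_of(next(iter(unvisited)), adj, unvisited)
        root = max(component, key=lambda r: (graph.read_lengths.get(r, 0), _neg_id(r)))
        phi[root] = +1
        queue = deque([root])
        seen = {root}
        while queue:
            u = queue.popleft()
            roots[u] = root
            for v in adj[u]:
                if v in seen:
                    continue
                seen.add(v)
                phi[v] = phi[u] * graph.edge(u, v).signature
                queue.append(v)
        unvisited -= component
    return phi, roots


class _neg_id(str):
    """Reverses lexicographic comparison so max() prefers the smaller id."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)


def _component_of(start: str, adj: dict[str, list[str]], universe: set[str]) -> set[str]:
    seen = {start}
    queue = deque([start])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v in universe and v not in seen:
                seen.add(v)
                queue.append(v)
    return seen


def prune_nonorientable(graph: OverlapGraph) -> tuple[OverlapGraph, OrientationResult]:
    """Remove every non-tree edge whose signature contradicts phi.

    Returns the orientable subgraph (a new ``OverlapGraph`` sharing edge
    objects) and the orientation bookkeeping.
    """
    forest = max_weight_spanning_forest(graph)
    phi, roots = assign_phi(graph, forest)
    removed: set[tuple[str, str]] = set()
    pruned = OverlapGraph(
        vertices=set(graph.vertices),
        read_lengths=dict(graph.read_lengths),
        contained=dict(graph.contained),
    )
    for key, edge in graph.edges.items():
        u, v = key
        if key not in forest and phi[u] * phi[v] != edge.signature:
            removed.add(key)
        else:
            pruned.edges[key] = edge
    return pruned, OrientationResult(forest=forest, phi=phi, removed_edges=removed, roots=roots)
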