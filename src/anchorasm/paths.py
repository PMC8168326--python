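"""Contig-path extraction from the directed acyclic overlap graph.

On perfect data the DAG is a directed proper interval graph whose triangle
reduction is a single path — the golden path covering a chromosome.  Real
graphs deviate by tips, bubbles and crosslinks, so paths are chosen greedily
by *interval support*: for every read r, the closed out-neighborhood is
approximated by a transitive tournament (its unique Hamiltonian path would be
a local golden path), and each arc is credited by the tournaments containing
it, discounted by the distance from the tournament's root.  Arcs inside many
locally proper-interval neighborhoods thus outrank spurious crosslinks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .graph import OverlapEdge
from .dag import DirectedOverlapGraph


@dataclass(frozen=True)
class TournamentApprox:
    """Best local transitive-tournament candidate rooted at one read."""

    root: str
    path: tuple[str, ...]
    h: int  # induced-arc count on the path (completeness proxy)
    arcs: frozenset  # induced arcs restricted to the path's vertices (H_r)


@dataclass
class ContigPath:
    vertices: tuple[str, ...]
    kind: str  # primary | tip | bubble | singleton
    arcs: list = field(default_factory=list)  # OverlapEdge payload per consecutive pair

    def __len__(self) -> int:
        return len(self.vertices)


def triangle_reduction(d: DirectedOverlapGraph) -> DirectedOverlapGraph:
    """Drop every arc u->w shortcutting a two-arc path u->v->w.

    Removal decisions are taken simultaneously on the input arc set.
    """
    out_adj: dict[str, set[str]] = {v: set() for v in d.vertices}
    for (u, v) in d.arcs:
        out_adj[u].add(v)
    keep = {
        (u, w): wgt
        for (u, w), wgt in d.arcs.items()
        if not any(w in out_adj[v] for v in out_adj[u] if v != w)
    }
    return DirectedOverlapGraph(
        vertices=set(d.vertices),
        arcs=keep,
        edge_payload={a: e for a, e in d.edge_payload.items() if a in keep},
    )


def tournament_approx(d: DirectedOverlapGraph, root: str, max_paths: int = 5000) -> TournamentApprox:
    """Approximate the maximal transitive tournament atop ``root``.

    Works inside the subgraph induced by the closed out-neighborhood of
    ``root``: its triangle reduction is traversed from ``root`` to every
    endpoint (vertex without outgoing arc in the induced subgraph) and the
    path maximising the induced-arc count h is kept (ties: smaller endpoint
    id, then lexicographic vertex sequence).
    """
    nplus = {root} | {v for (u, v) in d.arcs if u == root}
    induced = {(u, v) for (u, v) in d.arcs if u in nplus and v in nplus}
    if not induced:
        raise ValueError(f"root {root!r} has out-degree 0")
    sub = DirectedOverlapGraph(vertices=nplus, arcs={a: 0.0 for a in induced})
    red = triangle_reduction(sub)
    red_adj: dict[str, list[str]] = {v: [] for v in nplus}
    for (u, v) in red.arcs:
        red_adj[u].append(v)
    for adjacency in red_adj.values():
        adjacency.sort()

    paths: list[tuple[str, ...]] = []
    stack: list[tuple[str, ...]] = [(root,)]
    while stack and len(paths) < max_paths:
        path = stack.pop()
        nxt = red_adj[path[-1]]
        if not nxt:
            paths.append(path)
            continue
        for v in reversed(nxt):
            stack.append(path + (v,))
    induced_arcs = induced

    def h_of(path: tuple[str, ...]) -> int:
        vset = set(path)
        return sum(1 for (u, v) in induced_arcs if u in vset and v in vset)

    best = min(paths, key=lambda p: (-h_of(p), p[-1], p))
    vset = set(best)
    h_r = frozenset((u, v) for (u, v) in induced_arcs if u in vset and v in vset)
    return TournamentApprox(root=root, path=best, h=h_of(best), arcs=h_r)


def interval_support(d: DirectedOverlapGraph) -> dict[tuple[str, str], float]:
    """Distance-discounted tournament support nu for every arc.

    ``nu(e) = sum over roots r with e in H_r of 1 / (1 + d(r, e))`` where
    ``d(r, e)`` is the number of path arcs preceding e's tail on the root's
    tournament path.  Defined (possibly 0) for every arc of the triangle
    reduction.
    """
    reduced = triangle_reduction(d)
    nu: dict[tuple[str, str], float] = dict.fromkeys(reduced.arcs, 0.0)
    roots = {u for (u, _) in d.arcs}
    for root in sorted(roots):
        ta = tournament_approx(d, root)
        pos = {v: i for i, v in enumerate(ta.path)}
        for (u, v) in ta.arcs:
            dist = pos[u]
            nu[(u, v)] = nu.get((u, v), 0.0) + 1.0 / (1.0 + dist)
    return nu


def extract_paths(
    d: DirectedOverlapGraph,
    nu: dict[tuple[str, str], float] | None = None,
    min_rescue_len: int = 5,
) -> tuple[list[ContigPath], list[ContigPath]]:
    """Greedy visited-marking path extraction on the triangle reduction.

    Each round seeds at the remaining arc of maximal interval support (ties:
    larger Omega, then lexicographic arc key) and extends in both directions,
    choosing at every junction the in-/out-arc of maximal support.  A path is
    a primary contig if it has >= 2 reads and neither end touches an already
    visited neighborhood; otherwise it is a tip (one end) or bubble (both)
    and is kept only when at least ``min_rescue_len`` reads long.  Extracted
    nodes and their arcs are removed; the procedure ends on the empty graph.

    Returns ``(accepted, discarded)``.
    """
    if nu is None:
        nu = interval_support(d)
    reduced = triangle_reduction(d)
    orig_in: dict[str, set[str]] = {v: set() for v in reduced.vertices}
    orig_out: dict[str, set[str]] = {v: set() for v in reduced.vertices}
    for (u, v) in reduced.arcs:
        orig_out[u].add(v)
        orig_in[v].add(u)

    arcs = dict(reduced.arcs)  # arc -> Omega weight
    out_adj: dict[str, set[str]] = {v: set(vs) for v, vs in orig_out.items()}
    in_adj: dict[str, set[str]] = {v: set(vs) for v, vs in orig_in.items()}
    remaining = set(reduced.vertices)
    visited: set[str] = set()
    accepted: list[ContigPath] = []
    discarded: list[ContigPath] = []

    def arc_rank(a: tuple[str, str]) -> tuple:
        return (nu.get(a, 0.0), arcs[a], _RevKey(a))

    while remaining:
        if arcs:
            seed = max(arcs, key=arc_rank)
            path = [seed[0], seed[1]]
        else:
            path = [min(remaining)]
        # forward extension
        while True:
            nxt = [(path[-1], v) for v in out_adj[path[-1]] if v not in path]
            if not nxt:
                break
            path.append(max(nxt, key=arc_rank)[1])
        # backward extension
        while True:
            prv = [(u, path[0]) for u in in_adj[path[0]] if u not in path]
            if not prv:
                break
            path.insert(0, max(prv, key=arc_rank)[0])

        left_visited = bool(orig_in[path[0]] & visited)
        right_visited = bool(orig_out[path[-1]] & visited)
        if len(path) >= 2 and not left_visited and not right_visited:
            kind = "primary"
            keep = True
        else:
            kind = "bubble" if (left_visited and right_visited) else "tip"
            keep = len(path) >= min_rescue_len
        contig = ContigPath(
            vertices=tuple(path),
            kind=kind,
            arcs=[d.edge_payload.get((a, b)) for a, b in zip(path, path[1:])],
        )
        (accepted if keep else discarded).append(contig)

        for v in path:
            visited.add(v)
            remaining.discard(v)
            for w in out_adj.pop(v, set()):
                arcs.pop((v, w), None)
                in_adj.get(w, set()).discard(v)
            for u in in_adj.pop(v, set()):
                arcs.pop((u, v), None)
                out_adj.get(u, set()).discard(v)
    return accepted, discarded


class _RevKey(tuple):
    """max() with this key prefers the lexicographically smaller arc on ties."""

    def __lt__(self, other):
        return tuple.__gt__(self, other)
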