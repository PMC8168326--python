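"""Consensus sequence construction for contig paths.

Each contig path carries, per edge, the chained unitig anchors shared by the
two incident reads.  A shared unitig between different edges does not imply
the same genomic copy, so occurrences are first clustered: per unitig s, an
auxiliary graph over the path edges containing s links edge pairs that share
an interval on s, and a greedy clique cover yields a clique index c; a second
run index g separates occurrences interrupted along the path by an edge
lacking s (repeat suspicion).  Triples (s, c, g) become the nodes of a layout
multigraph M whose arcs connect occurrences adjacent on a path edge, with the
intervening long-read sequence (or a negative offset for overlapping unitigs)
as spacer.  M is acyclic; fixing one node per component and propagating in
topological order yields a common contig coordinate system.  The projection
emits high-quality unitig sequence wherever available and fills the gaps from
the best-covering long read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from ._util import revcomp
from .graph import MatchPair, project_s_interval
from .paths import ContigPath

logger = logging.getLogger(__name__)


class LayoutCycleError(RuntimeError):
    """The layout multigraph unexpectedly contains a cycle."""


@dataclass(frozen=True)
class OccurrenceMember:
    """One appearance of a unitig occurrence on one path edge."""

    edge_idx: int
    pair: MatchPair
    s_interval: tuple[int, int]  # intersection of the two anchors on s


@dataclass
class OccurrenceNode:
    key: tuple[str, int, int]  # (unitig id, clique index c, run index g)
    s_interval: tuple[int, int]  # union over member intervals
    strand: int  # orientation on the contig
    members: list[OccurrenceMember] = field(default_factory=list)


@dataclass
class LayoutMultigraph:
    nodes: dict[tuple[str, int, int], OccurrenceNode] = field(default_factory=dict)
    #: chosen arc per ordered node pair: (from, to) -> spacer length (bp, may
    #: be negative for overlapping unitigs)
    arcs: dict[tuple[tuple, tuple], int] = field(default_factory=dict)
    coordinates: dict[tuple, tuple[int, int]] = field(default_factory=dict)
    read_offsets: dict[str, int] = field(default_factory=dict)
    phi: dict[str, int] = field(default_factory=dict)
    contig_span: tuple[int, int] = (0, 0)


def _phi_interval(interval: tuple[int, int], length: int, phi: int) -> tuple[int, int]:
    """Map a native read interval into the read's phi-oriented frame."""
    a, b = interval
    if phi == +1:
        return a, b
    return length - b, length - a


def _edge_reads(path: ContigPath, edge_idx: int) -> tuple[str, str]:
    return path.vertices[edge_idx], path.vertices[edge_idx + 1]


def _member_matches(pair: MatchPair, read_id: str):
    """The anchor of ``pair`` lying on ``read_id``."""
    return pair.m1 if pair.m1.read_id == read_id else pair.m2


def path_edge_occurrences(path: ContigPath) -> list[dict[str, OccurrenceMember]]:
    """Per path edge: unitig id -> occurrence member (pairs with a shared
    s-interval only; anchors whose unitig intervals are disjoint carry no
    positional information)."""
    occ: list[dict[str, OccurrenceMember]] = []
    for idx, edge in enumerate(path.arcs):
        here: dict[str, OccurrenceMember] = {}
        if edge is not None:
            for pair in edge.chain:
                lo = max(pair.m1.s_start, pair.m2.s_start)
                hi = min(pair.m1.s_end, pair.m2.s_end)
                if hi > lo:
                    here[pair.unitig_id] = OccurrenceMember(idx, pair, (lo, hi))
        occ.append(here)
    return occ


def cluster_occurrences(
    occ_by_edge: list[dict[str, OccurrenceMember]]
) -> dict[tuple[str, int], int]:
    """Clique index c per (unitig, edge): a greedy cover of the auxiliary
    graph linking edge pairs that overlap on the unitig."""
    by_unitig: dict[str, list[OccurrenceMember]] = {}
    for here in occ_by_edge:
        for s, member in here.items():
            by_unitig.setdefault(s, []).append(member)
    cliques: dict[tuple[str, int], int] = {}
    for s, members in by_unitig.items():
        members.sort(key=lambda m: m.edge_idx)
        pending = list(members)
        c = 0
        while pending:
            clique = [pending.pop(0)]
            rest = []
            for m in pending:
                if all(
                    min(m.s_interval[1], q.s_interval[1]) > max(m.s_interval[0], q.s_interval[0])
                    for q in clique
                ):
                    clique.append(m)
                else:
                    rest.append(m)
            for m in clique:
                cliques[(s, m.edge_idx)] = c
            pending = rest
            c += 1
    return cliques


def assign_run_indices(
    occ_by_edge: list[dict[str, OccurrenceMember]]
) -> dict[tuple[str, int], int]:
    """Run index g per (unitig, edge): split when an intervening path edge
    lacks the unitig (disconnected occurrence)."""
    runs: dict[tuple[str, int], int] = {}
    unitigs = {s for here in occ_by_edge for s in here}
    for s in unitigs:
        g = 0
        prev_idx: int | None = None
        for idx, here in enumerate(occ_by_edge):
            if s not in here:
                continue
            if prev_idx is not None and idx > prev_idx + 1:
                g += 1
            runs[(s, idx)] = g
            prev_idx = idx
    return runs


def _read_offsets(path: ContigPath, phi: dict[str, int], read_lengths: dict[str, int]) -> dict[str, int]:
    """Contig-frame offset of every read, chained along the path edges.

    Each step projects the best shared anchor's unitig intersection onto both
    incident reads; the projections denote the same genomic stretch, so the
    phi-frame starts must coincide in contig coordinates.
    """
    offsets = {path.vertices[0]: 0}
    for idx, edge in enumerate(path.arcs):
        u, v = _edge_reads(path, idx)
        if edge is None:
            offsets[v] = offsets[u]
            continue
        pair = max(edge.chain, key=lambda p: (p.omega, p.unitig_id))
        lo = max(pair.m1.s_start, pair.m2.s_start)
        hi = min(pair.m1.s_end, pair.m2.s_end)
        if hi <= lo:  # disjoint unitig intervals carry no shared position
            lo, hi = pair.m1.s_start, pair.m1.s_end
        m_u = _member_matches(pair, u)
        m_v = _member_matches(pair, v)
        lo_u, hi_u = max(lo, m_u.s_start), min(hi, m_u.s_end)
        lo_v, hi_v = max(lo, m_v.s_start), min(hi, m_v.s_end)
        fu = _phi_interval(project_s_interval(m_u, lo_u, hi_u), read_lengths[u], phi[u])
        fv = _phi_interval(project_s_interval(m_v, lo_v, hi_v), read_lengths[v], phi[v])
        offsets[v] = offsets[u] + fu[0] - fv[0]
    return offsets


def _member_frame_interval(
    node: OccurrenceNode,
    member: OccurrenceMember,
    read_id: str,
    phi: dict[str, int],
    read_lengths: dict[str, int],
) -> tuple[int, int]:
    """Interval of the node's consensus unitig stretch in the phi-frame of
    one member read (clipped to the anchor, then extended to the union)."""
    m = _member_matches(member.pair, read_id)
    a, b = node.s_interval
    ca, cb = max(a, m.s_start), min(b, m.s_end)
    p, q = project_s_interval(m, ca, cb)
    sigma = m.orientation * phi[read_id]  # orientation on the contig frame
    fp, fq = _phi_interval((p, q), read_lengths[read_id], phi[read_id])
    if sigma == +1:
        start = fp - (ca - a)
    else:
        start = fp - (b - cb)
    return start, start + (b - a)


def build_layout(
    path: ContigPath,
    phi: dict[str, int],
    read_lengths: dict[str, int],
) -> LayoutMultigraph:
    """Cluster unitig occurrences and fix the contig coordinate system.

    Arcs connect occurrence nodes adjacent on a path edge (no third unitig
    strictly between); where multiple edges connect the same node pair the
    arc from the highest-Omega edge is kept.  One node per weak component is
    anchored through its most reliable member anchor; the rest follow in
    topological order.
    """
    occ_by_edge = path_edge_occurrences(path)
    cliques = cluster_occurrences(occ_by_edge)
    runs = assign_run_indices(occ_by_edge)
    offsets = _read_offsets(path, phi, read_lengths)

    layout = LayoutMultigraph(read_offsets=offsets, phi={r: phi[r] for r in path.vertices})
    member_key: dict[tuple[str, int], tuple[str, int, int]] = {}
    for idx, here in enumerate(occ_by_edge):
        for s, member in here.items():
            key = (s, cliques[(s, idx)], runs[(s, idx)])
            member_key[(s, idx)] = key
            node = layout.nodes.get(key)
            if node is None:
                u, _ = _edge_reads(path, idx)
                m = _member_matches(member.pair, u)
                layout.nodes[key] = node = OccurrenceNode(
                    key=key,
                    s_interval=member.s_interval,
                    strand=m.orientation * phi[u],
                )
            node.members.append(member)
            node.s_interval = (
                min(node.s_interval[0], member.s_interval[0]),
                max(node.s_interval[1], member.s_interval[1]),
            )

    # multi-arcs between occurrences adjacent on an edge; keep best edge's arc
    best_arc: dict[tuple[tuple, tuple], tuple[float, int, int]] = {}
    for idx, here in enumerate(occ_by_edge):
        if not here:
            continue
        u, _ = _edge_reads(path, idx)
        edge = path.arcs[idx]

        def frame_of(member: OccurrenceMember) -> tuple[int, int]:
            key = member_key[(member.pair.unitig_id, idx)]
            return _member_frame_interval(layout.nodes[key], member, u, phi, read_lengths)

        ordered = sorted(here.values(), key=lambda m: frame_of(m))
        for ma, mb in zip(ordered, ordered[1:]):
            ka = member_key[(ma.pair.unitig_id, idx)]
            kb = member_key[(mb.pair.unitig_id, idx)]
            if ka == kb:
                continue
            spacer = frame_of(mb)[0] - frame_of(ma)[1]
            cand = (edge.score, -idx, spacer)
            if (ka, kb) not in best_arc or cand > best_arc[(ka, kb)]:
                best_arc[(ka, kb)] = cand
    layout.arcs = {pair: cand[2] for pair, cand in best_arc.items()}

    _assign_coordinates(layout, path, offsets, phi, read_lengths)
    lo = min(offsets[r] for r in path.vertices)
    hi = max(offsets[r] + read_lengths[r] for r in path.vertices)
    layout.contig_span = (lo, hi)
    return layout


def _assign_coordinates(layout, path, offsets, phi, read_lengths) -> None:
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(layout.nodes)
    for (ka, kb), spacer in layout.arcs.items():
        g.add_edge(ka, kb, spacer=spacer)
    if not nx.is_directed_acyclic_graph(g):
        raise LayoutCycleError("layout multigraph contains a cycle")

    def anchor(key) -> int:
        node = layout.nodes[key]
        member = max(
            node.members,
            key=lambda m: (m.pair.m1.delta + m.pair.m2.delta, -m.edge_idx),
        )
        u, _ = _edge_reads(path, member.edge_idx)
        start, _ = _member_frame_interval(node, member, u, phi, read_lengths)
        return offsets[u] + start

    for key in nx.topological_sort(g):
        node = layout.nodes[key]
        width = node.s_interval[1] - node.s_interval[0]
        preds = [p for p in g.predecessors(key) if p in layout.coordinates]
        if preds:
            # propagate along the chosen arc from the rightmost placed parent
            p = max(preds, key=lambda pk: (layout.coordinates[pk][1], pk))
            start = layout.coordinates[p][1] + g[p][key]["spacer"]
        else:
            start = anchor(key)
        layout.coordinates[key] = (start, start + width)


def project_sequence(
    layout: LayoutMultigraph,
    path: ContigPath,
    unitig_seqs: dict[str, str],
    read_seqs: dict[str, str],
) -> tuple[str, list[tuple]]:
    """Assemble the contig string and its placement table.

    Unitig sequence (reverse-complemented for negative contig strand) is
    emitted at unitig-covered coordinates; gaps are filled from the deepest-
    covering long read in its phi-oriented frame.  Overlaps are resolved in
    favour of unitigs; among conflicting unitigs the earlier (higher-anchor)
    placement wins and the overlap of the later one is trimmed.
    """
    phi = layout.phi
    offsets = layout.read_offsets
    lo, hi = layout.contig_span

    def read_frame_seq(rid: str) -> str:
        seq = read_seqs[rid]
        return seq if phi[rid] == +1 else revcomp(seq)

    def fill_from_reads(x: int, y: int, pieces: list, placements: list) -> None:
        while x < y:
            best = None
            for rid in path.vertices:
                s0 = offsets[rid]
                s1 = s0 + len(read_seqs[rid])
                if s0 <= x < s1:
                    end = min(s1, y)
                    cand = (end, -s0, rid)
                    if best is None or cand > best:
                        best = cand
            if best is None:
                nxt = min(
                    (offsets[r] for r in path.vertices if offsets[r] > x),
                    default=y,
                )
                nxt = min(nxt, y)
                pieces.append("N" * (nxt - x))
                placements.append(("gap", "gap", x, nxt, "."))
                x = nxt
                continue
            end, _, rid = best
            fseq = read_frame_seq(rid)
            pieces.append(fseq[x - offsets[rid] : end - offsets[rid]])
            placements.append((rid, "long-read", x, end, "+" if phi[rid] == +1 else "-"))
            x = end

    nodes = sorted(
        layout.nodes,
        key=lambda k: (layout.coordinates[k][0], layout.coordinates[k][1], k),
    )
    pieces: list[str] = []
    placements: list[tuple] = []
    cur = lo
    for key in nodes:
        start, end = layout.coordinates[key]
        if end <= cur:
            continue  # fully shadowed by an earlier unitig
        if start > cur:
            fill_from_reads(cur, start, pieces, placements)
        node = layout.nodes[key]
        a, b = node.s_interval
        useq = unitig_seqs[key[0]][a:b]
        if node.strand == -1:
            useq = revcomp(useq)
        trim = cur - start if start < cur else 0
        pieces.append(useq[trim:])
        placements.append(
            (key[0], "unitig", max(start, cur), end, "+" if node.strand == +1 else "-")
        )
        cur = end
    if cur < hi:
        fill_from_reads(cur, hi, pieces, placements)

    seq = "".join(pieces)
    shifted = [(eid, etype, s - lo, e - lo, strand) for eid, etype, s, e, strand in placements]
    return seq, shifted


def consensus_for_path(
    path: ContigPath,
    phi: dict[str, int],
    unitig_seqs: dict[str, str],
    read_seqs: dict[str, str],
) -> tuple[str, list[tuple]] | None:
    """Full consensus for one contig path; None if the layout is cyclic."""
    read_lengths = {r: len(read_seqs[r]) for r in path.vertices}
    if len(path.vertices) == 1:
        rid = path.vertices[0]
        p = phi.get(rid, +1)
        seq = read_seqs[rid] if p == +1 else revcomp(read_seqs[rid])
        return seq, [(rid, "long-read", 0, len(seq), "+" if p == +1 else "-")]
    try:
        layout = build_layout(path, phi, read_lengths)
    except LayoutCycleError:
        logger.error("cyclic layout graph; contig %s dropped", "-".join(path.vertices[:3]))
        return None
    return project_sequence(layout, path, unitig_seqs, read_seqs)
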