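"""Long-read overlap graph built from unitig anchors.

Two long reads overlap when they share a *significant match* to the same
unitig.  Per read pair, the shared anchors are chained (classical colinear
chaining by dynamic programming) into the best mutually consistent subset;
the summed bit score Omega weighs the resulting undirected edge, which also
carries the relative orientation (signature), the spanning intervals of the
overlap on both reads, and the local direction of extension.  Reads fully
contained in a neighbor are contracted into it.

Coordinates are 0-based half-open throughout; the interpolation and score
formulas operate on inclusive endpoints internally (length j-i+1 == end-start).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

from ._util import round_half_up

logger = logging.getLogger(__name__)

DEFAULT_MIN_ANCHOR_BP = 500
DEFAULT_MIN_EDGE_SCORE = 500.0
DEFAULT_GAP_ABS = 400
DEFAULT_GAP_FRAC = 0.3
DEFAULT_MAX_OVERHANG = float("inf")  # dovetail screen off unless set


@dataclass(frozen=True)
class SignificantMatch:
    """A unitig-to-long-read anchor mapping above the exact-match threshold."""

    unitig_id: str
    read_id: str
    s_start: int
    s_end: int
    r_start: int
    r_end: int
    orientation: int  # theta(s, r) in {+1, -1}
    delta: int  # exactly aligned base pairs

    def __post_init__(self) -> None:
        if self.orientation not in (-1, 1):
            raise ValueError("orientation must be +1 or -1")
        if not (self.s_start < self.s_end and self.r_start < self.r_end):
            raise ValueError("empty match interval")


def significant_matches(paf, min_anchor_bp: int = DEFAULT_MIN_ANCHOR_BP) -> list[SignificantMatch]:
    """Keep PAF records with at least ``min_anchor_bp`` exactly aligned bp.

    PAF queries are unitigs, targets are long reads.  Multiple records for
    the same (unitig, read) pair are merged by keeping the highest-scoring
    one (ties: the earlier record).
    """
    best: dict[tuple[str, str], SignificantMatch] = {}
    for rec in paf:
        if rec.n_matches < min_anchor_bp:
            continue
        m = SignificantMatch(
            unitig_id=rec.query_id,
            read_id=rec.target_id,
            s_start=rec.query_start,
            s_end=rec.query_end,
            r_start=rec.target_start,
            r_end=rec.target_end,
            orientation=+1 if rec.strand == "+" else -1,
            delta=rec.n_matches,
        )
        key = (m.unitig_id, m.read_id)
        if key not in best or m.delta > best[key].delta:
            best[key] = m
    return list(best.values())


# ---------------------------------------------------------------------------
# coordinate transfer (linear interpolation between match endpoints)


def tau(i: int, j: int, ip: int, jp: int, h: int) -> int:
    """Interpolated position on the read for position ``h`` on the unitig.

    All arguments are inclusive coordinates of a match [i,j] on the unitig
    and [i',j'] on the read.  Anchored at the nearer endpoint so endpoint
    positions map exactly to endpoint positions; rounded half-up.
    """
    if not (i <= h <= j):
        raise ValueError(f"position {h} outside match interval [{i},{j}]")
    ratio = (jp - ip + 1) / (j - i + 1)
    if j - h <= h - i:
        return round_half_up(jp - (j - h) * ratio)
    return round_half_up(ip + (h - i) * ratio)


def tau_match(match: SignificantMatch, h: int) -> int:
    """``tau`` evaluated through a match's stored intervals (inclusive ``h``)."""
    return tau(match.s_start, match.s_end - 1, match.r_start, match.r_end - 1, h)


def project_s_interval(match: SignificantMatch, a: int, b: int) -> tuple[int, int]:
    """Project the half-open unitig interval [a,b) onto the read.

    Orientation-aware: on a reverse-strand match the unitig interval maps to
    the mirrored position within the read match interval.
    """
    lo = tau_match(match, a)
    hi = tau_match(match, b - 1)
    if match.orientation == +1:
        return lo, hi + 1
    ip, jp = match.r_start, match.r_end - 1
    return ip + jp - hi, ip + jp - lo + 1


# ---------------------------------------------------------------------------
# pair scoring and chaining


def pair_score(m1: SignificantMatch, m2: SignificantMatch) -> float:
    """Expected bit score of the overlap implied by one shared unitig.

    Half the intersection length of the two unitig intervals, weighted by the
    mean exact-match density of the two anchors; 0 for disjoint intervals.
    """
    i, j = m1.s_start, m1.s_end - 1
    k, l = m2.s_start, m2.s_end - 1
    lo, hi = max(i, k), min(j, l)
    if hi < lo:
        return 0.0
    return 0.5 * (hi - lo + 1) * (m1.delta / (j - i + 1) + m2.delta / (l - k + 1))


@dataclass(frozen=True)
class MatchPair:
    """The two anchors of one unitig shared by a read pair."""

    m1: SignificantMatch
    m2: SignificantMatch

    @property
    def unitig_id(self) -> str:
        return self.m1.unitig_id

    @property
    def theta(self) -> int:
        return self.m1.orientation * self.m2.orientation

    @property
    def omega(self) -> float:
        return pair_score(self.m1, self.m2)


def _pairs_consistent(p: MatchPair, q: MatchPair, gap_abs: float, gap_frac: float) -> bool:
    """Can ``q`` directly follow ``p`` in a chain (p precedes q on r1)?

    Same implied signature; same relative order on both reads (reversed on r2
    for opposite-strand overlaps); the anchor-to-anchor distances on the two
    reads must agree within the gap tolerance.
    """
    if p.theta != q.theta:
        return False
    k1p, k1q = (p.m1.r_start, p.m1.r_end), (q.m1.r_start, q.m1.r_end)
    k2p, k2q = (p.m2.r_start, p.m2.r_end), (q.m2.r_start, q.m2.r_end)
    if not k1p < k1q:
        return False
    if p.theta == +1:
        if not k2p < k2q:
            return False
    else:
        if not k2q < k2p:
            return False
    d1 = q.m1.r_start - p.m1.r_start
    d2 = abs(q.m2.r_start - p.m2.r_start)
    return abs(d1 - d2) <= max(gap_abs, gap_frac * max(d1, d2))


def _chain_key(chain: tuple[MatchPair, ...]) -> tuple:
    return (chain[0].m1.r_start, tuple(p.unitig_id for p in chain))


def chain_matches(
    pairs: list[MatchPair],
    gap_abs: float = DEFAULT_GAP_ABS,
    gap_frac: float = DEFAULT_GAP_FRAC,
) -> tuple[list[MatchPair], float, int]:
    """Best consistent anchor chain for one read pair.

    Dynamic programming over anchors sorted by position on the first read
    (quadratic in the number of shared unitigs) maximising the summed bit
    score Omega.  Ties prefer the chain whose leftmost anchor starts earlier
    on r1, then the lexicographically smaller unitig-id sequence.

    Returns ``(chain, Omega, theta)``.
    """
    if not pairs:
        raise ValueError("chain_matches requires at least one shared unitig")
    order = sorted(
        range(len(pairs)),
        key=lambda idx: (
            pairs[idx].m1.r_start,
            pairs[idx].m1.r_end,
            pairs[idx].unitig_id,
        ),
    )
    items = [pairs[idx] for idx in order]
    n = len(items)
    score = [0.0] * n
    chain: list[tuple[MatchPair, ...]] = [()] * n
    for i in range(n):
        best_score = items[i].omega
        best_chain = (items[i],)
        for j in range(i):
            if not _pairs_consistent(items[j], items[i], gap_abs, gap_frac):
                continue
            cand_score = score[j] + items[i].omega
            cand_chain = chain[j] + (items[i],)
            if cand_score > best_score or (
                cand_score == best_score and _chain_key(cand_chain) < _chain_key(best_chain)
            ):
                best_score = cand_score
                best_chain = cand_chain
        score[i] = best_score
        chain[i] = best_chain
    best = 0
    for i in range(1, n):
        if score[i] > score[best] or (
            score[i] == score[best] and _chain_key(chain[i]) < _chain_key(chain[best])
        ):
            best = i
    sel = list(chain[best])
    return sel, score[best], sel[0].theta


# ---------------------------------------------------------------------------
# edge classification


DIR_FORWARD = "r1->r2"  # r1 extends the overlap to the left, r2 to the right
DIR_BACKWARD = "r1<-r2"
CONTAINED_R1 = "r1_contained"
CONTAINED_R2 = "r2_contained"


@dataclass(frozen=True)
class OverlapEdge:
    """An anchor-supported overlap between two long reads."""

    r1: str
    r2: str
    signature: int
    score: float
    chain: tuple[MatchPair, ...]
    span_r1: tuple[int, int]
    span_r2: tuple[int, int]
    direction: str

    def other(self, rid: str) -> str:
        return self.r2 if rid == self.r1 else self.r1


def classify_edge(
    r1: str,
    r2: str,
    chain: list[MatchPair],
    score: float,
    signature: int,
    len1: int,
    len2: int,
) -> OverlapEdge:
    """Attach spanning intervals and the local direction of extension.

    With spans [a1,b1) on r1 and [a2,b2) on r2 covering every chained anchor:
    for same-strand overlaps r1 extends r2 to the left iff a1 > a2 and to the
    right iff len1-b1 > len2-b2; for opposite strands the r2 overhangs are
    read from its other end (left iff a1 > len2-b2, right iff len1-b1 > a2).
    No extension on either side means r1 is contained in r2; extension on
    both sides means r2 is contained in r1.

    The overhangs are measured at a unitig position both reads share,
    extrapolating each anchor past a clipped end at its own scale, so reads
    whose ends fall inside the same anchor still compare exactly.
    """
    a1 = min(p.m1.r_start for p in chain)
    b1 = max(p.m1.r_end for p in chain)
    a2 = min(p.m2.r_start for p in chain)
    b2 = max(p.m2.r_end for p in chain)

    def virt(m: SignificantMatch, s: int) -> float:
        ratio = (m.r_end - m.r_start) / (m.s_end - m.s_start)
        if m.orientation == +1:
            return m.r_start + (s - m.s_start) * ratio
        return m.r_end - (s - m.s_start) * ratio

    first, last = chain[0], chain[-1]
    s_lo = max(first.m1.s_start, first.m2.s_start)
    s_hi = min(last.m1.s_end, last.m2.s_end)
    if s_lo >= first.m1.s_end or s_lo >= first.m2.s_end:
        s_lo = first.m1.s_start  # disjoint unitig intervals: fall back
    if s_hi <= last.m1.s_start or s_hi <= last.m2.s_start:
        s_hi = last.m1.s_end
    p1, q1 = virt(first.m1, s_lo), virt(last.m1, s_hi)
    p2, q2 = virt(first.m2, s_lo), virt(last.m2, s_hi)
    left1, right1 = p1, len1 - q1
    if signature == +1:
        left2, right2 = p2, len2 - q2
    else:
        # the contig-left point sits near r2's native end and vice versa
        left2, right2 = len2 - p2, q2
    ext_left = left1 > left2
    ext_right = right1 > right2
    if not ext_left and not ext_right:
        direction = CONTAINED_R1
    elif ext_left and ext_right:
        direction = CONTAINED_R2
    elif ext_left:
        direction = DIR_FORWARD
    else:
        direction = DIR_BACKWARD
    return OverlapEdge(
        r1=r1,
        r2=r2,
        signature=signature,
        score=score,
        chain=tuple(chain),
        span_r1=(a1, b1),
        span_r2=(a2, b2),
        direction=direction,
    )


# ---------------------------------------------------------------------------
# graph assembly with containment contraction


@dataclass
class OverlapGraph:
    """Undirected signed, Omega-weighted overlap graph on long reads."""

    vertices: set[str] = field(default_factory=set)
    read_lengths: dict[str, int] = field(default_factory=dict)
    edges: dict[tuple[str, str], OverlapEdge] = field(default_factory=dict)
    #: contained read -> (container, signature theta(read, container),
    #:                     span on read, span on container)
    contained: dict[str, tuple[str, int, tuple[int, int], tuple[int, int]]] = field(
        default_factory=dict
    )

    def edge(self, u: str, v: str) -> OverlapEdge | None:
        return self.edges.get((u, v) if u < v else (v, u))

    def iter_edges(self):
        for key in sorted(self.edges):
            yield self.edges[key]

    def neighbors(self, u: str):
        for (a, b) in self.edges:
            if a == u:
                yield b
            elif b == u:
                yield a

    def n_components(self) -> int:
        import networkx as nx

        return nx.number_connected_components(self.to_networkx())

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.vertices)
        for (u, v), e in self.edges.items():
            g.add_edge(u, v, weight=e.score, signature=e.signature)
        return g


def _containment_transfer(
    edge: "OverlapEdge", child: str, parent: str
) -> tuple[int, tuple[int, int], tuple[int, int]]:
    """Anchor frame for re-targeting a contained read's matches.

    Projects the best shared anchor's unitig intersection onto both reads;
    the two projections denote the same genomic stretch and fix a unit-scale
    (mirrored for opposite strands) coordinate transfer child -> parent.
    """
    pair = max(edge.chain, key=lambda p: (p.omega, p.unitig_id))
    lo = max(pair.m1.s_start, pair.m2.s_start)
    hi = min(pair.m1.s_end, pair.m2.s_end)
    if hi <= lo:
        lo, hi = pair.m1.s_start, pair.m1.s_end
    m_c = pair.m1 if pair.m1.read_id == child else pair.m2
    m_t = pair.m1 if pair.m1.read_id == parent else pair.m2
    pc = project_s_interval(m_c, max(lo, m_c.s_start), min(hi, m_c.s_end))
    pt = project_s_interval(m_t, max(lo, m_t.s_start), min(hi, m_t.s_end))
    return edge.signature, pc, pt


def _project_through_containment(
    match: SignificantMatch,
    container: str,
    theta_ct: int,
    pc: tuple[int, int],
    pt: tuple[int, int],
    container_len: int,
) -> SignificantMatch | None:
    """Re-target a contained read's anchor onto its container read.

    ``pc``/``pt`` are corresponding intervals on child and container; the
    transfer preserves lengths (anchor-local unit scale).
    """
    if theta_ct == +1:
        lo = pt[0] + (match.r_start - pc[0])
        hi = pt[0] + (match.r_end - pc[0])
    else:
        lo = pt[0] + (pc[1] - match.r_end)
        hi = pt[0] + (pc[1] - match.r_start)
    # clip to the container, trimming the unitig interval in step so the
    # interpolation ratio of the re-targeted anchor stays true
    cut_left = max(0, -lo)
    cut_right = max(0, hi - container_len)
    new_orient = match.orientation * theta_ct
    if new_orient == +1:
        s0, s1 = match.s_start + cut_left, match.s_end - cut_right
    else:
        s0, s1 = match.s_start + cut_right, match.s_end - cut_left
    lo, hi = lo + cut_left, hi - cut_right
    if hi <= lo or s1 <= s0:
        return None
    kept = (s1 - s0) / (match.s_end - match.s_start)
    return replace(
        match,
        read_id=container,
        r_start=lo,
        r_end=hi,
        s_start=s0,
        s_end=s1,
        orientation=new_orient,
        delta=max(1, min(round(match.delta * kept), s1 - s0, hi - lo)),
    )


def is_dovetail(edge: OverlapEdge, len1: int, len2: int, max_overhang: float) -> bool:
    """Does the anchor-covered overlap close near a read end on both sides?

    For a true overlap the covered region ends within ``max_overhang`` bp
    (anchor sparsity slack) of the physical end of at least one read on each
    side.  An overlap terminating internally in *both* reads on the same
    side cannot stem from a simple shared genomic interval and flags a
    spurious (typically chimeric) join.
    """
    (a1, b1), (a2, b2) = edge.span_r1, edge.span_r2
    if edge.signature == +1:
        left2, right2 = a2, len2 - b2
    else:
        left2, right2 = len2 - b2, a2
    closes_left = min(a1, left2) <= max_overhang
    closes_right = min(len1 - b1, right2) <= max_overhang
    return closes_left and closes_right


def _pair_edges(
    matches: dict[tuple[str, str], SignificantMatch],
    read_lengths: dict[str, int],
    min_edge_score: float,
    gap_abs: float,
    gap_frac: float,
    max_overhang: float = DEFAULT_MAX_OVERHANG,
) -> list[OverlapEdge]:
    by_unitig: dict[str, list[SignificantMatch]] = {}
    for m in matches.values():
        by_unitig.setdefault(m.unitig_id, []).append(m)
    shared: dict[tuple[str, str], list[MatchPair]] = {}
    for unitig_matches in by_unitig.values():
        unitig_matches.sort(key=lambda m: m.read_id)
        for ma, mb in itertools.combinations(unitig_matches, 2):
            shared.setdefault((ma.read_id, mb.read_id), []).append(MatchPair(ma, mb))
    edges = []
    for (r1, r2), pairs in sorted(shared.items()):
        chain, score, signature = chain_matches(pairs, gap_abs, gap_frac)
        if score < min_edge_score:
            continue
        chained = {p.unitig_id for p in chain}
        if any(p.unitig_id not in chained and p.omega >= min_edge_score for p in pairs):
            # the chain had to discard an anchor that is strong enough to
            # carry an edge by itself: the overlap evidence is self-
            # contradictory (chimeric join or unrecognised repeat)
            continue
        edge = classify_edge(r1, r2, chain, score, signature, read_lengths[r1], read_lengths[r2])
        if edge.direction in (DIR_FORWARD, DIR_BACKWARD) and not is_dovetail(
            edge, read_lengths[r1], read_lengths[r2], max_overhang
        ):
            continue
        edges.append(edge)
    return edges


def build_overlap_graph(
    matches: list[SignificantMatch],
    read_lengths: dict[str, int],
    min_edge_score: float = DEFAULT_MIN_EDGE_SCORE,
    gap_abs: float = DEFAULT_GAP_ABS,
    gap_frac: float = DEFAULT_GAP_FRAC,
    max_overhang: float = DEFAULT_MAX_OVERHANG,
    max_rounds: int = 100,
) -> OverlapGraph:
    """Build the overlap graph, contracting containments to a fixed point.

    Each round chains and classifies all read pairs sharing an anchor; every
    contained read is removed and its anchors are re-projected onto the
    container through the spanning-interval alignment, then pairs are
    recomputed.  Terminates when no containment remains.
    """
    active: dict[tuple[str, str], SignificantMatch] = {}
    for m in matches:
        key = (m.unitig_id, m.read_id)
        if key not in active or m.delta > active[key].delta:
            active[key] = m
    contained: dict[str, tuple[str, int, tuple[int, int], tuple[int, int]]] = {}
    removed_reads: set[str] = set()

    for _ in range(max_rounds):
        edges = _pair_edges(active, read_lengths, min_edge_score, gap_abs, gap_frac, max_overhang)
        containments = [e for e in edges if e.direction in (CONTAINED_R1, CONTAINED_R2)]
        if not containments:
            break
        containments.sort(key=lambda e: (-e.score, e.r1, e.r2))
        touched: set[str] = set()
        for e in containments:
            if e.r1 in touched or e.r2 in touched:
                continue
            if e.direction == CONTAINED_R1:
                child, parent = e.r1, e.r2
            else:
                child, parent = e.r2, e.r1
            if read_lengths[child] > read_lengths[parent]:
                # containment both ways is only possible through rounding;
                # keep the longer read
                logger.info("containment of longer read %s into %s; roles swapped", child, parent)
                child, parent = parent, child
            touched.add(child)
            touched.add(parent)
            _, pc, pt = _containment_transfer(e, child, parent)
            # full extent of the child projected onto the parent
            if e.signature == +1:
                ext = (pt[0] - pc[0], pt[0] + (read_lengths[child] - pc[0]))
            else:
                ext = (pt[0] + pc[1] - read_lengths[child], pt[0] + pc[1])
            ext = (max(0, ext[0]), min(read_lengths[parent], ext[1]))
            contained[child] = (parent, e.signature, pc, pt, ext)
            removed_reads.add(child)
            parent_matches = [m for m in active.values() if m.read_id == parent]
            for key in [k for k in active if k[1] == child]:
                m = active.pop(key)
                proj = _project_through_containment(
                    m, parent, e.signature, pc, pt, read_lengths[parent]
                )
                if proj is None:
                    continue
                # a transferred anchor that lands on a different unitig's
                # anchor on the container contradicts the container's own
                # sequence (chimeric child or repeat) — do not spread it
                conflicted = any(
                    pm.unitig_id != proj.unitig_id
                    and min(pm.r_end, proj.r_end) - max(pm.r_start, proj.r_start)
                    >= 0.5 * min(pm.r_end - pm.r_start, proj.r_end - proj.r_start)
                    for pm in parent_matches
                )
                if conflicted:
                    continue
                pkey = (proj.unitig_id, parent)
                if pkey not in active or proj.delta > active[pkey].delta:
                    active[pkey] = proj
    else:
        logger.warning("containment contraction did not reach a fixed point")
        edges = [
            e
            for e in _pair_edges(active, read_lengths, min_edge_score, gap_abs, gap_frac, max_overhang)
            if e.direction in (DIR_FORWARD, DIR_BACKWARD)
        ]

    graph = OverlapGraph()
    graph.vertices = {m.read_id for m in active.values()}
    graph.read_lengths = {r: read_lengths[r] for r in graph.vertices}
    graph.contained = contained
    for e in edges:
        if e.direction in (DIR_FORWARD, DIR_BACKWARD):
            graph.edges[(e.r1, e.r2)] = e
    return graph


def _edge_frame_transfer(edge: "OverlapEdge", src: str, dst: str):
    """Interval mapping from ``src`` read coordinates to ``dst`` coordinates
    through the edge's best shared anchor (unit scale, strand-aware)."""
    pair = max(edge.chain, key=lambda p: (p.omega, p.unitig_id))
    m_src = pair.m1 if pair.m1.read_id == src else pair.m2
    m_dst = pair.m2 if pair.m1.read_id == src else pair.m1
    lo = max(pair.m1.s_start, pair.m2.s_start)
    hi = min(pair.m1.s_end, pair.m2.s_end)
    if hi <= lo:
        lo, hi = pair.m1.s_start, pair.m1.s_end
    ps = project_s_interval(m_src, max(lo, m_src.s_start), min(hi, m_src.s_end))
    pd = project_s_interval(m_dst, max(lo, m_dst.s_start), min(hi, m_dst.s_end))
    theta = edge.signature

    def transfer(x: int, y: int) -> tuple[int, int]:
        if theta == +1:
            return pd[0] + (x - ps[0]), pd[0] + (y - ps[0])
        return pd[0] + (ps[1] - y), pd[0] + (ps[1] - x)

    return transfer


def flag_chimeric_reads(
    matches: list[SignificantMatch],
    read_lengths: dict[str, int],
    min_edge_score: float = DEFAULT_MIN_EDGE_SCORE,
    gap_abs: float = DEFAULT_GAP_ABS,
    gap_frac: float = DEFAULT_GAP_FRAC,
    bridge_margin: int = 200,
    contradiction_overlap: int = 800,
    min_contradictions: int = 1,
) -> set[str]:
    """Chimera-suspect reads, detected on the pre-contraction overlap edges.

    A genuine read's neighbors occupy a genomic interval around it, so the
    overlap spans of its neighbors tile the read contiguously: even neighbor
    groups that share no edges among themselves (anchor dropout) leave span
    intervals on the read that overlap.  At a chimeric junction no genuine
    sequence crosses the joint: the neighbor groups stay unlinked *and*
    their span intervals stop on either side of the junction.  A read whose
    neighborhood components cannot be chained across it with at least
    ``bridge_margin`` bp of span overlap becomes a suspect.

    Sparse anchors can split a genuine read's neighborhood the same way, so a
    suspect is only removed when corroborated by anchor *contradictions*: an
    anchor of a neighbor that projects at least ``contradiction_overlap`` bp
    into the read's physical range (through the shared-anchor frame transfer)
    yet is absent from the read, or vice versa.  A genuine bridge has no such
    contradictions — where its anchors are sparse, so are its neighbors' —
    while reads overlapping a chimeric junction disagree about the sequence
    beyond it.

    Run before containment contraction — contraction would both thin the
    neighborhoods of genuine long reads and spread a contained chimera's
    far-locus anchors onto its container.
    """
    active: dict[tuple[str, str], SignificantMatch] = {}
    for m in matches:
        key = (m.unitig_id, m.read_id)
        if key not in active or m.delta > active[key].delta:
            active[key] = m
    by_unitig: dict[str, list[SignificantMatch]] = {}
    for m in active.values():
        by_unitig.setdefault(m.unitig_id, []).append(m)
    shared: dict[tuple[str, str], list[MatchPair]] = {}
    for unitig_matches in by_unitig.values():
        unitig_matches.sort(key=lambda m: m.read_id)
        for ma, mb in itertools.combinations(unitig_matches, 2):
            shared.setdefault((ma.read_id, mb.read_id), []).append(MatchPair(ma, mb))

    # edges plus, per read, the count of edges whose chain had to exclude a
    # strong shared anchor for inconsistency.  A chimera joining two nearby
    # loci keeps a connected neighborhood, but reads spanning its junction
    # share anchors with it whose implied offsets disagree, so the colinear
    # chain drops them on edge after edge.
    adj: dict[str, dict[str, OverlapEdge]] = {}
    n_edges_of: dict[str, int] = {}
    n_inconsistent_of: dict[str, int] = {}
    for (r1, r2), pairs in sorted(shared.items()):
        chain, score, signature = chain_matches(pairs, gap_abs, gap_frac)
        if score < min_edge_score:
            continue
        e = classify_edge(r1, r2, chain, score, signature, read_lengths[r1], read_lengths[r2])
        adj.setdefault(e.r1, {})[e.r2] = e  # containment edges included
        adj.setdefault(e.r2, {})[e.r1] = e
        chained = {p.unitig_id for p in chain}
        excluded_strong = any(
            p.unitig_id not in chained and p.omega >= min_edge_score for p in pairs
        )
        for rid in (r1, r2):
            n_edges_of[rid] = n_edges_of.get(rid, 0) + 1
            if excluded_strong:
                n_inconsistent_of[rid] = n_inconsistent_of.get(rid, 0) + 1
    suspects: set[str] = set()
    for r in sorted(n_inconsistent_of):
        if n_inconsistent_of[r] >= 2 and n_inconsistent_of[r] >= 0.3 * n_edges_of[r]:
            suspects.add(r)
    for r in sorted(adj):
        nbrs = set(adj[r])
        if len(nbrs) < 2:
            continue
        comps: list[set[str]] = []
        left = set(nbrs)
        while left:
            seen: set[str] = set()
            stack = [min(left)]
            while stack:
                u = stack.pop()
                if u in seen:
                    continue
                seen.add(u)
                stack.extend(set(adj[u]) & left - seen)
            comps.append(seen)
            left -= seen
        if len(comps) == 1:
            continue

        def span_on_r(n: str) -> tuple[int, int]:
            e = adj[r][n]
            return e.span_r1 if r == e.r1 else e.span_r2

        comp_ivs = sorted(
            (min(span_on_r(n)[0] for n in c), max(span_on_r(n)[1] for n in c))
            for c in comps
        )
        split = False
        reach_end = None
        for a, b in comp_ivs:
            if reach_end is not None and a > reach_end - bridge_margin:
                split = True
                break
            reach_end = b if reach_end is None else max(reach_end, b)
        if not split:
            continue

        # corroborate: cross-project anchors between r and each neighbor
        matches_of: dict[str, list[SignificantMatch]] = {}
        for m in active.values():
            if m.read_id == r or m.read_id in nbrs:
                matches_of.setdefault(m.read_id, []).append(m)
        n_contra = 0
        for n in sorted(nbrs):
            e = adj[r][n]
            to_r = _edge_frame_transfer(e, n, r)
            to_n = _edge_frame_transfer(e, r, n)
            for m in matches_of.get(n, ()):
                if (m.unitig_id, r) in active:
                    continue
                x, y = to_r(m.r_start, m.r_end)
                if min(y, read_lengths[r]) - max(x, 0) >= contradiction_overlap:
                    n_contra += 1
            for m in matches_of.get(r, ()):
                if (m.unitig_id, n) in active:
                    continue
                x, y = to_n(m.r_start, m.r_end)
                if min(y, read_lengths[n]) - max(x, 0) >= contradiction_overlap:
                    n_contra += 1
        if n_contra >= min_contradictions:
            suspects.add(r)
    return suspects
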