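"""End-to-end assembly: filters -> overlap graph -> orientation -> DAG ->
contig paths -> consensus, with a per-stage run report."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

from . import consensus as consensus_mod
from . import dag as dag_mod
from . import filters as filters_mod
from . import graph as graph_mod
from . import orientation as orientation_mod
from . import paths as paths_mod
from .io import PafRecord, SequenceRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All user-facing thresholds of the assembly pipeline.

    ``min_anchor_bp`` is the minimum number of exactly aligned base pairs for
    a unitig-to-read match to count as an anchor; ``min_edge_score`` the
    minimum chained bit score Omega for an overlap edge.
    """

    min_anchor_bp: int = 500
    min_edge_score: float = 500.0
    gap_abs: int = 400
    gap_frac: float = 0.3
    max_overhang: float = float("inf")
    rescue_min_len: int = 500
    min_unitig_len: int = 500
    min_rescue_nodes: int = 5
    apply_unitig_filter: bool = True
    apply_chimera_filter: bool = True
    emit_singletons: bool = True

    def __post_init__(self) -> None:
        if min(self.min_anchor_bp, self.min_edge_score, self.rescue_min_len,
               self.min_unitig_len, self.min_rescue_nodes) <= 0:
            raise ValueError("all thresholds must be positive")


@dataclass
class AssemblyResult:
    contigs: list[tuple[str, str]]
    layout: list[tuple]
    report: dict
    graph: graph_mod.OverlapGraph | None = None
    directed: dag_mod.DirectedOverlapGraph | None = None
    contig_paths: list[paths_mod.ContigPath] = field(default_factory=list)
    phi: dict[str, int] = field(default_factory=dict)


def _clip_paf_to_fragments(
    paf: list[PafRecord], kept_unitigs: list[SequenceRecord]
) -> list[PafRecord]:
    """Restrict PAF records to the surviving unitigs and rescued fragments.

    A rescued fragment ``uid:rescue:a-b`` inherits the records of ``uid``
    clipped to [a, b), with the read interval and match count scaled
    proportionally.
    """
    fragments: dict[str, list[tuple[str, int, int]]] = {}
    for u in kept_unitigs:
        if ":rescue:" in u.id:
            base, region = u.id.rsplit(":rescue:", 1)
            a, b = (int(x) for x in region.split("-"))
            fragments.setdefault(base, []).append((u.id, a, b))
    kept_ids = {u.id for u in kept_unitigs}
    out: list[PafRecord] = []
    for rec in paf:
        if rec.query_id in kept_ids:
            out.append(rec)
            continue
        for fid, a, b in fragments.get(rec.query_id, []):
            lo, hi = max(rec.query_start, a), min(rec.query_end, b)
            if hi <= lo:
                continue
            frac_lo = (lo - rec.query_start) / (rec.query_end - rec.query_start)
            frac_hi = (hi - rec.query_start) / (rec.query_end - rec.query_start)
            t_span = rec.target_end - rec.target_start
            t0 = rec.target_start + round(frac_lo * t_span)
            t1 = rec.target_start + round(frac_hi * t_span)
            if rec.strand == "-":
                t0, t1 = rec.target_end - (t1 - rec.target_start), \
                         rec.target_end - (t0 - rec.target_start)
            if t1 <= t0:
                continue
            n_match = max(1, min(round(rec.n_matches * (frac_hi - frac_lo)),
                                 hi - lo, t1 - t0))
            out.append(
                PafRecord(
                    query_id=fid, query_len=b - a,
                    query_start=lo - a, query_end=hi - a,
                    strand=rec.strand,
                    target_id=rec.target_id, target_len=rec.target_len,
                    target_start=t0, target_end=t1,
                    n_matches=n_match, block_len=max(hi - lo, t1 - t0),
                    mapq=rec.mapq,
                )
            )
    return out


def assemble(
    unitigs: list[SequenceRecord],
    long_reads: list[SequenceRecord],
    paf: list[PafRecord],
    config: PipelineConfig = PipelineConfig(),
) -> AssemblyResult:
    """Run the full pipeline and return contigs, layout and the run report."""
    report: dict = {"config": asdict(config)}
    read_seqs = {r.id: r.seq for r in long_reads}
    read_lengths = {r.id: r.length for r in long_reads}

    if config.apply_unitig_filter and paf:
        unitigs, filt_report = filters_mod.filter_unitigs_by_coverage(
            unitigs, paf,
            rescue_min_len=config.rescue_min_len,
            min_unitig_len=config.min_unitig_len,
        )
        paf = _clip_paf_to_fragments(paf, unitigs)
        report["unitig_filter"] = filt_report
    unitig_seqs = {u.id: u.seq for u in unitigs}

    matches = graph_mod.significant_matches(paf, min_anchor_bp=config.min_anchor_bp)
    report["n_significant_matches"] = len(matches)
    if not matches:
        logger.warning("no significant anchors; nothing to assemble")
        report.update(n_contigs=0, total_bp=0)
        return AssemblyResult(contigs=[], layout=[], report=report)

    if config.apply_chimera_filter:
        suspects = graph_mod.flag_chimeric_reads(
            matches, read_lengths,
            min_edge_score=config.min_edge_score,
            gap_abs=config.gap_abs, gap_frac=config.gap_frac,
        )
        matches = [m for m in matches if m.read_id not in suspects]
        report["chimera_filter"] = {"n_removed_reads": len(suspects)}

    graph = graph_mod.build_overlap_graph(
        matches, read_lengths,
        min_edge_score=config.min_edge_score,
        gap_abs=config.gap_abs, gap_frac=config.gap_frac,
        max_overhang=config.max_overhang,
    )
    report["overlap_graph"] = {
        "n_vertices": len(graph.vertices),
        "n_edges": len(graph.edges),
        "n_contained": len(graph.contained),
    }

    pruned, orient = orientation_mod.prune_nonorientable(graph)
    report["orientation"] = {
        "n_removed_edges": len(orient.removed_edges),
        "n_edges": len(pruned.edges),
    }

    directed = dag_mod.orient_arcs(pruned, orient.phi)
    order, feedback = dag_mod.modified_kahn(directed)
    directed.topo_order = order
    directed.feedback_set = feedback
    forest, forest_changed = dag_mod.repair_spanning_forest(pruned, orient.forest, feedback)
    acyclic = directed.without_feedback()
    report["dag"] = {
        "n_feedback_arcs": len(feedback),
        "forest_repaired": forest_changed,
        "n_arcs": len(acyclic.arcs),
    }

    nu = paths_mod.interval_support(acyclic) if acyclic.arcs else {}
    accepted, discarded = paths_mod.extract_paths(
        acyclic, nu, min_rescue_len=config.min_rescue_nodes
    )
    if config.emit_singletons:
        placed = {v for p in accepted for v in p.vertices}
        for v in sorted(acyclic.vertices):
            if v in placed:
                continue
            if not acyclic.in_neighbors(v) and not acyclic.out_neighbors(v):
                accepted.append(paths_mod.ContigPath(vertices=(v,), kind="singleton"))
    report["paths"] = {
        "n_accepted": len(accepted),
        "n_discarded": len(discarded),
        "kinds": {k: sum(1 for p in accepted if p.kind == k)
                  for k in ("primary", "tip", "bubble", "singleton")},
    }

    contigs: list[tuple[str, str]] = []
    layout_rows: list[tuple] = []
    n_dropped = 0
    for i, path in enumerate(accepted):
        result = consensus_mod.consensus_for_path(path, orient.phi, unitig_seqs, read_seqs)
        if result is None:
            n_dropped += 1
            continue
        seq, placements = result
        cid = f"contig_{i + 1:04d}"
        contigs.append((cid, seq))
        layout_rows.extend((cid, *row) for row in placements)
    report["n_contigs"] = len(contigs)
    report["n_dropped_cyclic"] = n_dropped
    report["total_bp"] = sum(len(s) for _, s in contigs)

    return AssemblyResult(
        contigs=contigs,
        layout=layout_rows,
        report=report,
        graph=pruned,
        directed=acyclic,
        contig_paths=accepted,
        phi=orient.phi,
    )
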