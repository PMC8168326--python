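"""Readers and writers for the standard formats the pipeline touches.

Sequences are FASTA/FASTQ (plain or gzip) parsed with Biopython; anchor
mappings are PAF as emitted by long-read mappers such as minimap2.  All
internal coordinates are 0-based half-open, the PAF convention.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (a long read or a unitig)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record with empty id")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class PafRecord:
    """One mapping line of the 12 mandatory PAF columns.

    ``n_matches`` (column 10) is the number of exactly aligned base pairs;
    it is the matching score of a unitig-to-long-read anchor.
    """

    query_id: str
    query_len: int
    query_start: int
    query_end: int
    strand: str
    target_id: str
    target_len: int
    target_start: int
    target_end: int
    n_matches: int
    block_len: int
    mapq: int

    def __post_init__(self) -> None:
        for side, start, end, ln in (
            ("query", self.query_start, self.query_end, self.query_len),
            ("target", self.target_start, self.target_end, self.target_len),
        ):
            if not (0 <= start < end <= ln):
                raise ValueError(
                    f"invalid {side} interval [{start},{end}) on length {ln}"
                )
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.n_matches > self.block_len:
            raise ValueError("n_matches exceeds block_len")


def _open_text(path: str | Path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _sniff_format(path: str | Path) -> str:
    with _open_text(path) as fh:
        for line in fh:
            if line.strip():
                if line.startswith(">"):
                    return "fasta"
                if line.startswith("@"):
                    return "fastq"
                raise ValueError(f"{path}: not FASTA or FASTQ (first line {line[:20]!r})")
    return "fasta"  # empty file: arbitrary


def read_sequences(path: str | Path, format: str = "auto") -> list[SequenceRecord]:
    """Read FASTA/FASTQ (plain or gzip) into a list of records.

    Order is preserved; sequence ids are taken up to the first whitespace
    (mapper convention); duplicate ids raise ``ValueError``.
    """
    if format == "auto":
        format = _sniff_format(path)
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unknown sequence format {format!r}")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, format):
            rid = rec.id  # Biopython already splits at whitespace
            if rid in seen:
                raise ValueError(f"{path}: duplicate sequence id {rid!r}")
            seen.add(rid)
            records.append(SequenceRecord(rid, str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def parse_paf(path: str | Path) -> list[PafRecord]:
    """Parse a PAF file (>=12 tab-separated columns; extras ignored)."""
    records: list[PafRecord] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ValueError(f"{path}:{lineno}: PAF line has {len(cols)} < 12 columns")
            try:
                records.append(
                    PafRecord(
                        query_id=cols[0],
                        query_len=int(cols[1]),
                        query_start=int(cols[2]),
                        query_end=int(cols[3]),
                        strand=cols[4],
                        target_id=cols[5],
                        target_len=int(cols[6]),
                        target_start=int(cols[7]),
                        target_end=int(cols[8]),
                        n_matches=int(cols[9]),
                        block_len=int(cols[10]),
                        mapq=int(cols[11]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return records


def format_paf(rec: PafRecord) -> str:
    return "\t".join(
        str(x)
        for x in (
            rec.query_id,
            rec.query_len,
            rec.query_start,
            rec.query_end,
            rec.strand,
            rec.target_id,
            rec.target_len,
            rec.target_start,
            rec.target_end,
            rec.n_matches,
            rec.block_len,
            rec.mapq,
        )
    )


def write_paf(records: Iterable[PafRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(format_paf(rec) + "\n")


# ---------------------------------------------------------------------------
# assembly output


def write_gfa(graph, path: str | Path) -> None:
    """Export an overlap graph as GFA 1.0.

    Segments are long reads; links are overlap edges.  The edge signature is
    stored in a ``th:i`` tag, the chained bit score in ``om:f``.
    """
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for rid in sorted(graph.vertices):
            length = graph.read_lengths.get(rid)
            seg = f"S\t{rid}\t*"
            if length is not None:
                seg += f"\tLN:i:{length}"
            fh.write(seg + "\n")
        for edge in graph.iter_edges():
            fh.write(
                f"L\t{edge.r1}\t+\t{edge.r2}\t{'+' if edge.signature > 0 else '-'}"
                f"\t0M\tth:i:{edge.signature}\tom:f:{edge.score:.1f}\n"
            )


def write_outputs(contigs, layout, graph, out_prefix: str | Path) -> dict:
    """Write contig FASTA, layout TSV and (if a graph is given) GFA.

    ``contigs`` is an iterable of ``(id, sequence)``; ``layout`` an iterable
    of placement rows ``(contig_id, element_id, element_type, start, end,
    strand)`` in 0-based half-open contig coordinates.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    contigs = list(contigs)
    fasta_path = out_prefix.with_suffix(".fasta")
    write_fasta((SequenceRecord(cid, seq) for cid, seq in contigs), fasta_path)
    layout_path = out_prefix.with_suffix(".layout.tsv")
    with open(layout_path, "w") as fh:
        fh.write("contig\telement\ttype\tstart\tend\tstrand\n")
        for row in layout:
            fh.write("\t".join(str(x) for x in row) + "\n")
    paths = {"contigs": str(fasta_path), "layout": str(layout_path)}
    if not contigs:
        logger.warning("no contigs to write; emitting empty FASTA/layout")
    if graph is not None:
        gfa_path = out_prefix.with_suffix(".gfa")
        write_gfa(graph, gfa_path)
        paths["gfa"] = str(gfa_path)
    return paths
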