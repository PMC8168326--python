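"""Anchor preparation filters.

Two independent screens keep repetitive sequence out of the anchor set:

1. a k-mer abundance filter on the short reads — reads carrying k-mers far
   more abundant than the main coverage peak are likely repeat-derived and
   are removed before unitig assembly;
2. a mapping-coverage outlier filter on the unitigs — unitigs whose maximal
   long-read mapping coverage exceeds ``Q3 + 1.5*IQR`` over the unitig set
   are flagged as repeats; sub-regions of a flagged unitig with coverage at
   or below Q3 spanning more than ``rescue_min_len`` bp are rescued as new
   anchor fragments.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .io import PafRecord, SequenceRecord
from ._util import revcomp

logger = logging.getLogger(__name__)


@dataclass
class KmerProfile:
    """Canonical k-mer abundance histogram over a read set."""

    k: int
    counts: dict[str, int] = field(repr=False)

    @property
    def histogram(self) -> dict[int, int]:
        """abundance -> number of distinct canonical k-mers at that abundance."""
        hist: dict[int, int] = {}
        for c in self.counts.values():
            hist[c] = hist.get(c, 0) + 1
        return hist


@dataclass
class CoverageProfile:
    """Per-base long-read mapping coverage of one unitig."""

    unitig_id: str
    per_base: np.ndarray

    @property
    def max_cov(self) -> int:
        return int(self.per_base.max()) if self.per_base.size else 0


def iter_canonical_kmers(seq: str, k: int):
    """Yield canonical (strand-collapsed) k-mers, skipping any containing N."""
    seq = seq.upper()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        rc = revcomp(kmer)
        yield kmer if kmer <= rc else rc


def build_kmer_profile(reads: list[SequenceRecord], k: int) -> KmerProfile:
    """Count canonical k-mers over all reads."""
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: dict[str, int] = {}
    for rec in reads:
        for kmer in iter_canonical_kmers(rec.seq, k):
            counts[kmer] = counts.get(kmer, 0) + 1
    if reads and not counts:
        logger.warning("k=%d exceeds every read length; empty k-mer profile", k)
    return KmerProfile(k=k, counts=counts)


def detect_abundance_cutoff(profile: KmerProfile, override: int | None = None) -> float:
    """Place the abundance cutoff right next to the main coverage peak.

    The histogram of a shotgun read set has an error valley after abundance 1
    and a main peak near the sequencing coverage.  The cutoff is the smallest
    abundance above the peak where the histogram has fallen to half the peak
    height; k-mers more abundant than this are treated as repetitive.
    Returns ``math.inf`` (no filtering) when no peak exists beyond the valley.
    """
    if override is not None:
        return override
    hist = profile.histogram
    if not hist:
        logger.warning("empty k-mer profile; no abundance cutoff")
        return math.inf
    abundances = sorted(hist)
    counts = [hist[a] for a in abundances]
    n = len(abundances)
    # error valley: first local minimum after abundance 1
    valley_idx = None
    for i in range(1, n):
        left = counts[i - 1]
        right = counts[i + 1] if i + 1 < n else math.inf
        if counts[i] <= left and counts[i] <= right:
            valley_idx = i
            break
    if valley_idx is None or valley_idx == n - 1:
        logger.warning("no main k-mer peak beyond the error valley; no cutoff applied")
        return math.inf
    peak_idx = max(range(valley_idx + 1, n), key=lambda i: (counts[i], -i))
    peak_count = counts[peak_idx]
    for i in range(peak_idx + 1, n):
        if counts[i] <= peak_count / 2:
            return abundances[i]
    logger.warning("histogram never falls to half maximum beyond the peak; no cutoff")
    return math.inf


def filter_short_reads(
    reads: list[SequenceRecord], profile: KmerProfile, cutoff: float
) -> tuple[list[SequenceRecord], dict]:
    """Remove reads containing any canonical k-mer with abundance > cutoff."""
    kept: list[SequenceRecord] = []
    for rec in reads:
        if any(profile.counts.get(km, 0) > cutoff for km in iter_canonical_kmers(rec.seq, profile.k)):
            continue
        kept.append(rec)
    report = {
        "n_input": len(reads),
        "n_retained": len(kept),
        "fraction_retained": len(kept) / len(reads) if reads else 1.0,
        "cutoff": cutoff,
    }
    return kept, report


def coverage_profiles(
    unitigs: list[SequenceRecord], paf: list[PafRecord]
) -> dict[str, CoverageProfile]:
    """Per-base coverage of each unitig by its long-read mappings (PAF queries)."""
    lengths = {u.id: u.length for u in unitigs}
    deltas = {u.id: np.zeros(u.length + 1, dtype=np.int32) for u in unitigs}
    for rec in paf:
        if rec.query_id not in deltas:
            raise ValueError(f"PAF query {rec.query_id!r} not in unitig set")
        d = deltas[rec.query_id]
        d[rec.query_start] += 1
        d[rec.query_end] -= 1
    return {
        uid: CoverageProfile(uid, np.cumsum(deltas[uid][: lengths[uid]]))
        for uid in deltas
    }


def filter_unitigs_by_coverage(
    unitigs: list[SequenceRecord],
    paf: list[PafRecord],
    rescue_min_len: int = 500,
    min_unitig_len: int = 500,
) -> tuple[list[SequenceRecord], dict]:
    """Drop coverage-outlier unitigs, rescuing their low-coverage sub-regions.

    Quartiles of the maximal-coverage distribution use linear interpolation
    between order statistics (numpy default).  A unitig is an outlier when
    ``max_cov > Q3 + 1.5*IQR``; within an outlier, maximal runs with per-base
    coverage <= Q3 longer than ``rescue_min_len`` bp are emitted as renamed
    fragments.  Fragments and unitigs below ``min_unitig_len`` are dropped.
    """
    if not paf:
        logger.warning("empty mapping set; all unitigs pass the coverage filter")
        kept = [u for u in unitigs if u.length >= min_unitig_len]
        return kept, {"q1": None, "q3": None, "n_flagged": 0, "n_rescued": 0,
                      "n_input": len(unitigs), "n_output": len(kept)}
    profiles = coverage_profiles(unitigs, paf)
    max_covs = np.array([profiles[u.id].max_cov for u in unitigs], dtype=float)
    q1, q3 = np.percentile(max_covs, [25, 75])
    threshold = q3 + 1.5 * (q3 - q1)
    out: list[SequenceRecord] = []
    n_flagged = n_rescued = 0
    for u in unitigs:
        if u.length < min_unitig_len:
            continue
        prof = profiles[u.id]
        if prof.max_cov <= threshold:
            out.append(u)
            continue
        n_flagged += 1
        ok = prof.per_base <= q3
        # maximal runs of positions with coverage <= Q3
        start = None
        for pos in range(u.length + 1):
            inside = pos < u.length and ok[pos]
            if inside and start is None:
                start = pos
            elif not inside and start is not None:
                if pos - start > rescue_min_len and pos - start >= min_unitig_len:
                    out.append(
                        SequenceRecord(f"{u.id}:rescue:{start}-{pos}", u.seq[start:pos])
                    )
                    n_rescued += 1
                start = None
    report = {
        "q1": float(q1),
        "q3": float(q3),
        "threshold": float(threshold),
        "n_flagged": n_flagged,
        "n_rescued": n_rescued,
        "n_input": len(unitigs),
        "n_output": len(out),
    }
    return out, report
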