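"""Synthetic genomes, unitig anchors, noisy long reads and ground-truth PAF.

The generator emulates the data regime the assembler targets: a random
genome (optionally with planted repeats), unique-region unitigs at roughly
regular spacing, low-coverage long reads with an InDel-dominated error
profile, optional chimeras and random strand, and the mapper's output as
ground-truth PAF records with configurable coordinate jitter and dropout.
Every step is driven by one seeded generator, so runs reproduce byte-
identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import PafRecord, SequenceRecord
from ._util import revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass(frozen=True)
class RepeatSpec:
    count: int
    length: int
    identity: float = 1.0  # fraction of copied bases left unmutated


@dataclass(frozen=True)
class SimulationConfig:
    genome_length: int = 100_000
    n_chromosomes: int = 1
    unitig_mean_len: int = 1_000
    unitig_spacing: int = 2_000
    read_len_mean: int = 8_000
    read_len_sd: int = 1_000
    min_read_len: int = 1_000
    coverage: float = 10.0
    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    chimera_rate: float = 0.0
    reverse_strand_prob: float = 0.5
    repeat_spec: RepeatSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.sub_rate, self.ins_rate, self.del_rate, self.chimera_rate,
                     self.reverse_strand_prob):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")

    @property
    def total_error(self) -> float:
        return self.sub_rate + self.ins_rate + self.del_rate

    def with_nanopore_errors(self, total: float, indel_sub_ratio: float = 4.0) -> "SimulationConfig":
        """Split a total per-bp error rate into sub/ins/del with the stated
        InDel:substitution ratio (InDels split evenly)."""
        sub = total / (1.0 + indel_sub_ratio)
        indel = total - sub
        return replace(self, sub_rate=sub, ins_rate=indel / 2, del_rate=indel / 2)


@dataclass(frozen=True)
class UnitigPlacement:
    unitig_id: str
    chrom: str
    start: int
    end: int
    strand: str
    in_repeat: bool = False


@dataclass(frozen=True)
class ReadSegment:
    """One genomic segment of a (possibly chimeric) long read.

    ``coord_map[i]`` is the read position (in the final read) where genomic
    offset ``i`` of the segment lands; monotone along the segment's strand.
    """

    chrom: str
    start: int
    end: int
    strand: str
    read_start: int
    read_end: int
    coord_map: np.ndarray = field(repr=False, hash=False, compare=False)

    def read_interval(self, g0: int, g1: int) -> tuple[int, int]:
        """Read coordinates of the genomic sub-interval [g0, g1)."""
        a = int(self.coord_map[g0 - self.start])
        b = int(self.coord_map[g1 - self.start])
        if self.strand == "+":
            return self.read_start + a, self.read_start + b
        seg_len = self.read_end - self.read_start
        return self.read_start + seg_len - b, self.read_start + seg_len - a


@dataclass(frozen=True)
class ReadTruth:
    read_id: str
    segments: tuple[ReadSegment, ...]

    @property
    def is_chimeric(self) -> bool:
        return len(self.segments) > 1

    @property
    def primary(self) -> ReadSegment:
        return max(self.segments, key=lambda s: s.end - s.start)


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: list[SequenceRecord]
    unitigs: list[SequenceRecord]
    unitig_truth: list[UnitigPlacement]
    reads: list[SequenceRecord]
    read_truth: dict[str, ReadTruth]
    paf: list[PafRecord]
    repeats: list[tuple[str, int, int]] = field(default_factory=list)


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def simulate_genome(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[list[SequenceRecord], list[tuple[str, int, int]]]:
    """Uniform random genome; planted repeats are copies of one template at
    the requested identity (to seed spurious anchors for filter tests)."""
    per_chrom = config.genome_length // config.n_chromosomes
    chroms = []
    arrays = {}
    for c in range(config.n_chromosomes):
        name = f"chr{c + 1}"
        arrays[name] = _random_seq(rng, per_chrom)
        chroms.append(name)
    repeats: list[tuple[str, int, int]] = []
    if config.repeat_spec is not None:
        spec = config.repeat_spec
        template = _random_seq(rng, spec.length)
        for _ in range(spec.count):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            arr = arrays[chrom]
            if len(arr) <= spec.length:
                continue
            pos = int(rng.integers(0, len(arr) - spec.length))
            copy = template.copy()
            n_mut = int(round((1.0 - spec.identity) * spec.length))
            if n_mut:
                sites = rng.choice(spec.length, size=n_mut, replace=False)
                copy[sites] = (copy[sites] + rng.integers(1, 4, size=n_mut)) % 4
            arr[pos : pos + spec.length] = copy
            repeats.append((chrom, pos, pos + spec.length))
    genome = [SequenceRecord(name, _decode(arrays[name])) for name in chroms]
    return genome, repeats


def simulate_unitigs(
    genome: list[SequenceRecord],
    config: SimulationConfig,
    rng: np.random.Generator,
    repeats: list[tuple[str, int, int]] | None = None,
    avoid_repeats: bool = True,
) -> tuple[list[SequenceRecord], list[UnitigPlacement]]:
    """Exact genomic substrings at ~regular spacing on random strands."""
    repeats = repeats or []
    unitigs: list[SequenceRecord] = []
    placements: list[UnitigPlacement] = []
    idx = 0
    for rec in genome:
        pos = config.unitig_spacing // 4
        while pos + config.unitig_mean_len < rec.length:
            length = int(
                np.clip(
                    rng.normal(config.unitig_mean_len, config.unitig_mean_len * 0.1),
                    config.unitig_mean_len // 2,
                    config.unitig_mean_len * 2,
                )
            )
            end = min(pos + length, rec.length)
            in_repeat = any(
                c == rec.id and s < end and pos < e for (c, s, e) in repeats
            )
            if in_repeat and avoid_repeats:
                pos += config.unitig_spacing
                continue
            strand = "+" if rng.random() >= 0.5 else "-"
            seq = rec.seq[pos:end]
            if strand == "-":
                seq = revcomp(seq)
            uid = f"u{idx:05d}"
            unitigs.append(SequenceRecord(uid, seq))
            placements.append(UnitigPlacement(uid, rec.id, pos, end, strand, in_repeat))
            idx += 1
            pos += config.unitig_spacing
    return unitigs, placements


def _apply_errors(
    codes: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Apply per-base substitutions, single-base insertions and deletions.

    Returns ``(read codes, coord_map)`` where ``coord_map`` has length
    ``len(codes) + 1`` and maps genomic offsets to read offsets.
    """
    n = len(codes)
    if config.total_error == 0.0:
        return codes.copy(), np.arange(n + 1, dtype=np.int64)
    dels = rng.random(n) < config.del_rate
    ins = rng.random(n) < config.ins_rate
    subs = (rng.random(n) < config.sub_rate) & ~dels
    out = codes.copy()
    if subs.any():
        k = int(subs.sum())
        out[subs] = (out[subs] + rng.integers(1, 4, size=k, dtype=np.uint8)) % 4
    keep = ~dels
    contrib = ins.astype(np.int64) + keep.astype(np.int64)
    prefix = np.concatenate(([0], np.cumsum(contrib)))
    total = int(prefix[-1])
    read = np.empty(total, dtype=np.uint8)
    ins_pos = prefix[:-1][ins]
    if len(ins_pos):
        read[ins_pos] = rng.integers(0, 4, size=len(ins_pos), dtype=np.uint8)
    base_pos = (prefix[:-1] + ins.astype(np.int64))[keep]
    read[base_pos] = out[keep]
    coord_map = prefix[:-1] + ins.astype(np.int64)
    coord_map = np.concatenate((coord_map, [total]))
    return read, coord_map


def simulate_long_reads(
    genome: list[SequenceRecord],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[SequenceRecord], dict[str, ReadTruth]]:
    """Sample reads to the target coverage with errors, strand and chimeras.

    Fragment start positions are drawn so that coverage is uniform across the
    chromosome including its ends: fragments overhanging an end are clipped,
    and clipped reads shorter than ``min_read_len`` are redrawn.
    """
    arrays = {rec.id: _CODE[np.frombuffer(rec.seq.encode(), dtype=np.uint8)] for rec in genome}
    chrom_ids = [rec.id for rec in genome]
    chrom_lens = np.array([rec.length for rec in genome], dtype=float)
    weights = chrom_lens / chrom_lens.sum()
    n_reads = int(round(config.coverage * sum(r.length for r in genome) / config.read_len_mean))
    reads: list[SequenceRecord] = []
    truth: dict[str, ReadTruth] = {}

    def sample_fragment(target_len: int) -> tuple[str, int, int]:
        for _ in range(100):
            chrom = chrom_ids[int(rng.choice(len(chrom_ids), p=weights))]
            clen = len(arrays[chrom])
            start = int(rng.integers(-(target_len - 1), clen - 1))
            end = min(start + target_len, clen)
            start = max(start, 0)
            if end - start >= min(config.min_read_len, target_len):
                return chrom, start, end
        return chrom, 0, min(target_len, clen)  # pragma: no cover

    for i in range(n_reads):
        rid = f"r{i:05d}"
        length = int(np.clip(rng.normal(config.read_len_mean, config.read_len_sd),
                             config.min_read_len, None))
        chimeric = rng.random() < config.chimera_rate
        n_seg = 2 if chimeric else 1
        seg_lens = [length // n_seg] * n_seg
        segments: list[ReadSegment] = []
        pieces: list[np.ndarray] = []
        offset = 0
        for seg_len in seg_lens:
            chrom, start, end = sample_fragment(seg_len)
            codes = arrays[chrom][start:end]
            read_codes, coord_map = _apply_errors(codes, config, rng)
            strand = "+" if rng.random() >= config.reverse_strand_prob else "-"
            if strand == "-":
                read_codes = (3 - read_codes)[::-1]
            segments.append(
                ReadSegment(
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    read_start=offset,
                    read_end=offset + len(read_codes),
                    coord_map=coord_map,
                )
            )
            pieces.append(read_codes)
            offset += len(read_codes)
        seq = _decode(np.concatenate(pieces))
        reads.append(SequenceRecord(rid, seq))
        truth[rid] = ReadTruth(read_id=rid, segments=tuple(segments))
    return reads, truth


def emit_true_paf(
    unitig_truth: list[UnitigPlacement],
    read_truth: dict[str, ReadTruth],
    config: SimulationConfig,
    rng: np.random.Generator,
    min_overlap: int = 500,
    jitter: int = 0,
    dropout_rate: float = 0.0,
) -> list[PafRecord]:
    """One PAF record per (unitig, read-segment) genomic overlap.

    Coordinates come from the per-read coordinate maps, the exact-match count
    is the overlap length scaled by one minus the combined substitution and
    deletion rate, interval ends are jittered symmetrically, and records are
    dropped at ``dropout_rate`` to emulate mapping noise.
    """
    by_chrom: dict[str, list[UnitigPlacement]] = {}
    for u in unitig_truth:
        by_chrom.setdefault(u.chrom, []).append(u)
    err = config.sub_rate + config.del_rate
    records: list[PafRecord] = []
    for rid in sorted(read_truth):
        rt = read_truth[rid]
        read_len = rt.segments[-1].read_end
        for seg in rt.segments:
            for u in by_chrom.get(seg.chrom, []):
                lo = max(seg.start, u.start)
                hi = min(seg.end, u.end)
                if hi - lo < min_overlap:
                    continue
                if dropout_rate and rng.random() < dropout_rate:
                    continue
                ulen = u.end - u.start
                if u.strand == "+":
                    s0, s1 = lo - u.start, hi - u.start
                else:
                    s0, s1 = u.end - hi, u.end - lo
                r0, r1 = seg.read_interval(lo, hi)
                strand = "+" if u.strand == seg.strand else "-"
                if jitter:
                    s0 += int(rng.integers(-jitter, jitter + 1))
                    s1 += int(rng.integers(-jitter, jitter + 1))
                    r0 += int(rng.integers(-jitter, jitter + 1))
                    r1 += int(rng.integers(-jitter, jitter + 1))
                    s0, s1 = max(0, min(s0, ulen - 1)), min(ulen, max(s1, 1))
                    r0, r1 = max(0, min(r0, read_len - 1)), min(read_len, max(r1, 1))
                    if s1 <= s0 or r1 <= r0:
                        continue
                n_match = int((hi - lo) * (1.0 - err))
                n_match = max(1, min(n_match, s1 - s0, r1 - r0))
                block = max(s1 - s0, r1 - r0)
                records.append(
                    PafRecord(
                        query_id=u.unitig_id,
                        query_len=ulen,
                        query_start=s0,
                        query_end=s1,
                        strand=strand,
                        target_id=rid,
                        target_len=read_len,
                        target_start=r0,
                        target_end=r1,
                        n_matches=n_match,
                        block_len=block,
                        mapq=60,
                    )
                )
    return records


def simulate_dataset(
    config: SimulationConfig,
    min_overlap: int = 500,
    jitter: int = 0,
    dropout_rate: float = 0.0,
) -> SimulatedDataset:
    """Run the full generator pipeline from one seed."""
    rng = np.random.default_rng(config.seed)
    genome, repeats = simulate_genome(config, rng)
    unitigs, unitig_truth = simulate_unitigs(genome, config, rng, repeats)
    reads, read_truth = simulate_long_reads(genome, config, rng)
    paf = emit_true_paf(
        unitig_truth, read_truth, config, rng,
        min_overlap=min_overlap, jitter=jitter, dropout_rate=dropout_rate,
    )
    return SimulatedDataset(
        config=config,
        genome=genome,
        unitigs=unitigs,
        unitig_truth=unitig_truth,
        reads=reads,
        read_truth=read_truth,
        paf=paf,
        repeats=repeats,
    )
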