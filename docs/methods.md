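# Methods

## Model and assumptions

`anchorasm` assembles long reads ℛ using a set 𝒮 of short-read unitigs as
anchors. The central assumption is that unitigs are (i) accurate at the
sequence level and (ii) unique in the genome, so that a unitig mapping to
two long reads implies those reads overlap. Both properties are promoted by
two filters: k-mer abundance filtering of the short reads before unitig
assembly, and mapping-coverage outlier filtering of the unitigs afterwards.
The pipeline never aligns long reads against each other; all coordinates on
long reads derive from anchor mappings via linear interpolation, so local
base-level accuracy inside anchor-free stretches is that of the raw reads.

Internally every interval is 0-based half-open. The scoring and
interpolation formulas are stated on inclusive endpoints (length = j−i+1)
and converted at the function boundary, so "interval length" means the same
number everywhere.

## Anchor preparation

**k-mer filter.** Canonical (strand-collapsed) k-mers are counted over the
short reads. The abundance histogram of a shotgun library has an error peak
at abundance 1–2, a valley, and a main peak near the coverage; repetitive
k-mers lie far right of the main peak. The cutoff is placed "right next to"
the main peak as the smallest abundance beyond it where the histogram falls
to half the peak height — a simple, fully automatic rule; the half-maximum
choice is this package's concretisation and can be overridden. Reads
containing any k-mer above the cutoff are dropped.

**Unitig coverage filter.** Per-base mapping coverage of each unitig by the
long reads is accumulated from the PAF intervals. Over the distribution of
per-unitig maximal coverages, quartiles are estimated by linear
interpolation of order statistics (the common type-7 rule), and unitigs
with max coverage above Q3 + 1.5·IQR are flagged as repeat-like. Inside a
flagged unitig, maximal runs with per-base coverage ≤ Q3 longer than
`rescue_min_len` (default 500 bp, also the minimum anchor length) are
rescued as renamed fragments; their PAF records are clipped proportionally.
Q3 in the rescue rule is the global Q3, not a per-unitig one. *Limitation:*
at ~10× coverage the sampling fluctuation of max coverage is comparable to
the IQR, so occasionally a run of unitigs over a genuine coverage spike is
flagged, costing local anchors (and with sparse anchors, contiguity). The
rule cannot distinguish such spikes from true two-copy repeats; it is kept
because repeat exclusion is what protects the overlap graph.

## Overlap graph

Significant matches are PAF records with ≥ `min_anchor_bp` (default 500)
exactly matching bases; split mappings of one (unitig, read) pair keep the
highest-scoring record. The coordinate transfer τ maps a unitig position to
a read position by linear interpolation anchored at the nearer match
endpoint, rounded half-up, so endpoints map to endpoints exactly. τ is
monotone up to a single-bp step where its two branches meet (they differ by
(len_s − len_r)/(len_s+1) < 1 bp when the read interval is the shorter
one) — an inherent property of the formula, harmless downstream.

Per read pair the shared anchors are chained by an O(n²) dynamic program
maximising Σω over subsets that agree in implied orientation and relative
order on both reads (order reversed on the second read for opposite-strand
overlaps) and whose consecutive anchor distances agree within
max(400 bp, 0.3·d). Ties prefer the chain starting earlier on the first
read, then the lexicographically smaller unitig sequence — determinism
throughout the pipeline is a design goal, so every selection in the code
has a total order. An edge is created when Ω ≥ `min_edge_score` (500).

**Extension and containment.** The chained anchors span an interval on each
read; comparing the overhangs beyond the overlap decides whether each read
extends the other to the left/right, yielding a direction, or neither/both,
yielding a containment. Overhangs are measured at a unitig position both
reads share, extrapolating each anchor linearly past a clipped end: two
reads that begin inside the same anchor then still compare exactly, which
matters because a missed containment becomes a (harmless but untidy)
parallel vertex. Contained reads are contracted iteratively; their anchors
re-target onto the container through a unit-scale, strand-aware transfer
anchored at the containment edge's best shared anchor, clipping unitig and
read intervals in step so interpolation ratios stay truthful. A transferred
anchor that would land on a different unitig's anchor on the container
contradicts the container's sequence and is discarded rather than spread.

**Chimera handling.** Chimeric reads are treated purely at the graph level:

* an edge whose chain had to discard a shared anchor strong enough to carry
  an edge by itself (ω ≥ `min_edge_score`) is self-contradictory and is
  dropped;
* before contraction, a read is removed when the components of its induced
  neighbourhood carry overlap-span intervals that cannot be chained across
  the read (≥ 200 bp mutual overlap), **and** at least one anchor of a
  neighbour projects ≥ 800 bp into the read's physical range while absent
  from it (or vice versa). The corroboration step protects genuine
  "sole-bridge" reads whose neighbourhood merely splits over an anchor-free
  stretch: there, neighbours have no anchors to contradict the read with.

An optional dovetail screen (overlap must close within `max_overhang` bp of
a read end on each side) exists but is off by default: at 2 kb anchor
spacing the overhang distributions of true and chimeric edges overlap too
much for a useful threshold.

## Orientation, DAG, paths

The signed graph is orientable iff every cycle has positive signature
product; checking a Kirchhoff cycle basis of an Ω-maximal spanning forest
suffices. φ is assigned by one traversal from a per-component reference
read (the longest; ties by id), and every violating non-tree edge is
deleted — always the Ω-minimum of its fundamental cycle, so the forest and
component count are preserved.

Arcs follow φ and the extension direction; the modified Kahn sort dequeues
sources by largest Ω-weight from the sorted prefix (heap with lazy
invalidation; ties by id) and, lacking a source, picks an "almost source"
among the prefix's unsorted out-neighbours K: a candidate without in-arcs
from K if one exists (largest prefix weight), else the candidate maximising
prefix weight minus K weight. Its remaining in-arcs form the feedback set,
which is exactly the back-arc set of the produced order. When K is empty
but unsorted vertices remain (entering a cyclic component), candidates are
the source strongly connected components of the unsorted subgraph, so
feedback arcs stay inside the component being broken — a fallback outside
the original description, chosen after a min-in-weight fallback measurably
overshot the feedback optimum by dequeuing sinks. If feedback arcs hit the
spanning forest, Kruskal simply reruns on the surviving edges.

Contigs are maximal paths in the triangle reduction (every arc shortcutting
a two-arc path removed, decisions taken on the input arc set in one pass).
Arc choice at junctions uses interval support
ν(e) = Σ_{roots r with e ∈ H_r} 1/(1 + d(r,e)), where H_r is the arc set of
the best transitive-tournament approximation of r's closed out-neighbourhood
(the maximal path through the neighbourhood's triangle reduction with the
most induced arcs h, ties to the smaller endpoint) and d(r,e) counts path
arcs before e's tail. The discounted form is this package's concrete
instantiation of "triangles supporting e". Extraction seeds each round at
the remaining arc of maximal ν (ties: larger Ω, then id) and extends both
ways greedily — taking the best-supported path first keeps tips from
truncating golden paths. A path is a primary contig with ≥ 2 reads and
unvisited end-neighbourhoods; otherwise a tip (one end visited) or bubble
(both), kept only at ≥ `min_rescue_nodes` (5) reads. Reads isolated in the
DAG are emitted as single-read contigs.

## Consensus

Within a contig path, occurrences of the same unitig on different edges are
clustered: a greedy clique cover of the auxiliary graph linking edges that
overlap on the unitig gives the clique index c (greedy cover replaces an
asymptotically better heuristic because the instances are path-local and
tiny), and a run index g splits occurrences interrupted by an edge lacking
the unitig (repeat suspicion). Triples (s, c, g) are the nodes of the
layout multigraph M, with the union of member intervals as the node's
consensus unitig stretch. Arcs connect occurrences adjacent on an edge; of
multiple arcs between two nodes, the one from the highest-Ω edge is kept,
its spacer being the signed distance between the projected consensus
intervals on the shared read. Coordinates propagate along chosen arcs in
topological order; each weak component of M is anchored through its most
reliable member anchor in the read-offset frame, which itself chains along
the path by projecting each edge's best shared anchor onto both incident
reads (the projections denote the same genomic stretch, so their
φ-oriented starts coincide). A cyclic M — not observed in practice — drops
the contig with a diagnostic. Projection emits unitig sequence
(reverse-complemented for negative contig strand) at unitig-covered
coordinates, resolving overlaps in favour of the earlier placement, and
fills gaps from the deepest-covering long read in its φ-oriented frame; the
placement table tiles the contig exactly. No polishing is applied.

## Synthetic data

The generator emulates the target regime: a uniform random genome
(optionally with planted repeat copies), exact unitigs of ~1 kb every 2 kb
on random strands, and long reads of mean 8 kb (sd 1 kb) at 10× with
per-base substitution/insertion/deletion errors, optional two-segment
chimeras and random strand. Fragment starts are drawn so coverage is
uniform across the chromosome including its ends (overhanging fragments are
clipped; reads under 1 kb redrawn) — the realistic fragmentation model, and
necessary for golden paths to reach the chromosome ends. The default noisy
profile splits total error 4:1 between InDels and substitutions (InDels
even between insertion and deletion), mimicking nanopore data. Ground-truth
PAF records are emitted per (unitig, read-segment) genomic overlap ≥ 500 bp
with exact coordinates from per-read coordinate maps, match counts scaled
by 1 − (substitution+deletion) rate, optional symmetric coordinate jitter,
and record dropout emulating mapping noise. Everything derives from one
seeded generator; runs reproduce byte-identically.

What the simulator does **not** model: realistic basecaller error profiles
(homopolymer compression, quality strings), coverage biases, adapter
sequence, and repeat families beyond simple planted copies. Passing tests
therefore demonstrate the graph-algorithmic correctness of the pipeline
under an idealised noise model, not production accuracy on real flowcell
data, where anchor uniqueness and mapping quality are the binding
constraints.

## Test problem sizes and numerical choices

End-to-end tests use a 100 kb single chromosome at 10× long-read coverage
(≈125 reads, ≈50 unitigs), which exercises every pipeline stage in well
under a minute; property tests run hundreds of random instances with ≤ 12
vertices where exhaustive oracles (cycle enumeration, subset-DP feedback
optimum, chain enumeration) are exact. The misassembly measure used against
simulation truth is QUAST-like: the left endpoints of a contig's
non-chimeric reads must be monotone up to a 1 kb relocation slack (chimeric
reads have no single truth position; sub-kb swaps of reads starting within
an anchor of each other are interpolation noise, not structural errors).
Floating-point scores are compared exactly where determinism guarantees
identical computation paths and with small absolute tolerances otherwise.
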