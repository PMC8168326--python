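# anchorasm

Hybrid genome assembly of **low-coverage long reads** using short-read
**unitig anchors**.

Long-read assemblers normally need 30–60× coverage and an all-vs-all read
comparison. `anchorasm` instead determines which long reads overlap from a
set of *anchors*: high-accuracy, repeat-depleted unitigs assembled from
cheap short-read data and mapped onto the long reads (e.g. with minimap2,
consumed here as PAF). Two long reads sharing an anchor overlap — no
read-vs-read alignment is ever computed — which makes the approach workable
down to ~5–10× long-read coverage.

## Method in brief

Given unitigs *s* ∈ 𝒮 mapped to long reads *r* ∈ ℛ with at least δ\* = 500
exactly matching bases:

1. **Overlap graph.** For each read pair sharing anchors, the anchors are
   chained by dynamic programming into the best mutually consistent subset;
   one shared unitig *s* with intervals [i,j] and [k,l] on *s* contributes
   the bit score
   ω(s,r₁,r₂) = ½ (min{j,l} − max{i,k} + 1) (δ(s,r₁)/(j−i+1) + δ(s,r₂)/(l−k+1)),
   and the chain's total Ω weighs the edge. Each edge carries the relative
   orientation θ(r₁,r₂) ∈ {±1}, the spanning overlap intervals, and the
   local direction of extension; reads contained in a neighbour are
   contracted into it. Anchor positions transfer between coordinate systems
   by endpoint-anchored linear interpolation (τ).
2. **Orientation.** An Ω-maximal spanning forest (Kruskal) fixes a vertex
   orientation φ by multiplying edge signatures along tree paths; every
   non-tree edge with φ(u)φ(v) ≠ θ(uv) closes a negative cycle and is
   deleted. The non-tree edge is always the Ω-minimum of its fundamental
   cycle, so the forest — and contiguity — survive.
3. **DAG.** Edges become arcs from φ and the extension direction. A
   modified Kahn topological sort breaks residual cycles: when no source
   exists, an "almost source" is chosen among the sorted set's unsorted
   out-neighbours and its remaining in-arcs form the feedback set F.
4. **Golden paths.** On ideal data the DAG is a directed proper interval
   graph whose triangle reduction is a single path per chromosome. Real
   graphs carry tips, bubbles and crosslinks, so paths are extracted
   greedily by *interval support* ν(e): each arc is credited by the local
   transitive-tournament approximations (out-neighbourhood Hamiltonian
   paths) that contain it, discounted by distance from the tournament root.
5. **Consensus.** Unitig occurrences along a path are clustered (clique
   index over shared unitig intervals, run index over path contiguity) into
   a layout multigraph that fixes one contig coordinate system; unitig
   sequence is emitted wherever available and long-read sequence fills the
   gaps.

Chimeric reads are handled at the graph level: edges whose anchor chains
are self-contradictory are dropped, and reads whose neighbourhoods fall
apart on them — corroborated by cross-projected anchor contradictions — are
removed before containment contraction.

## Worked example

```python
from anchorasm.pipeline import assemble
from anchorasm.simulate import SimulationConfig, simulate_dataset

ds = simulate_dataset(SimulationConfig(seed=0))   # 100 kb genome, 10x perfect reads
result = assemble(ds.unitigs, ds.reads, ds.paf)
```

Running `python examples/01_simulate_and_assemble.py` prints:

```
simulated 125 reads, 50 unitigs, 452 anchor mappings
overlap graph: 68 reads, 301 edges, 57 contained reads contracted
orientation removed 0 edges; feedback arc set size 0
contig_0001: 100000 bp, exact genome substring: True
```

125 error-free 8 kb reads at 10× collapse to 68 overlap-graph vertices
(57 nested reads are contracted); the graph is already orientable and
acyclic (nothing removed, F = ∅), one golden path covers the chromosome,
and the projected consensus reproduces the 100 kb genome exactly.
`examples/02_noisy_assembly.py` repeats this with 10 % InDel-dominated
errors, 2 % chimeric reads and 30 % anchor dropout, and
`examples/03_graph_stages.py` walks the orientation/DAG/extraction stages
on a hand-made graph.

The same pipeline is exposed as a CLI:

```
anchorasm simulate --seed 0 --out-dir sim/
anchorasm assemble --unitigs sim/unitigs.fa --long-reads sim/reads.fa \
    --paf sim/truth.paf --out asm
```

writing `asm.fasta`, a placement table `asm.layout.tsv`, a GFA 1.0 export
of the overlap graph and a JSON run report.

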