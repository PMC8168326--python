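"""Step through the graph stages on a small hand-made instance.

Five reads tile a toy region; one extra overlap edge carries a contradictory
relative orientation and is pruned, after which the graph is directed and
topologically sorted.
"""

from anchorasm.dag import modified_kahn, orient_arcs
from anchorasm.orientation import prune_nonorientable
from anchorasm.paths import extract_paths, interval_support

import sys
from pathlib import Path
sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "tests"))
from conftest import toy_edge, toy_graph

g = toy_graph([
    ("r1", "r2", +1, 900), ("r2", "r3", +1, 800), ("r3", "r4", +1, 850),
    ("r4", "r5", +1, 700), ("r1", "r3", +1, 400), ("r2", "r4", +1, 350),
    ("r2", "r5", -1, 100),  # orientation conflict: weakest edge of its cycle
])
for key, e in list(g.edges.items()):
    g.edges[key] = toy_edge(*key, signature=e.signature, score=e.score)

pruned, orient = prune_nonorientable(g)
print(f"removed for orientation: {sorted(orient.removed_edges)}")
print(f"phi: {dict(sorted(orient.phi.items()))}")

directed = orient_arcs(pruned, orient.phi)
order, feedback = modified_kahn(directed)
print(f"topological order: {order}, feedback arcs: {sorted(feedback)}")

nu = interval_support(directed)
accepted, discarded = extract_paths(directed, nu)
for p in accepted:
    print(f"{p.kind} path: {' -> '.join(p.vertices)}")
# The conflicting r2-r5 edge is deleted (its fundamental cycle has negative
# signature product and it is the Omega-minimum of that cycle); the rest
# orders into one contig path r1..r5.
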