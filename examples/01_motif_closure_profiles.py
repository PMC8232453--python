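"""Closure and clustering profiles of the canonical 3-node motifs.

Builds the feed-forward triangle (1->2, 2->3, 1->3) and the 3-cycle
(1->2, 2->3, 3->1) and prints each node's directed closure coefficient, its
source/target split, and the four pattern coefficients.  On the feed-forward
triangle every node has E^D = 0.5, but the split tells the roles apart: node
1 only ever *emits* the closing edge (E^src = 1), node 3 only receives it
(E^tgt = 1), and node 2 does both.  On the 3-cycle all triangles are cyclic,
so e_cyc = 1 everywhere and the source/target split is symmetric.
"""

from netclosure import (
    closure_patterns,
    local_directed_closure,
    motif_fixtures,
    source_target_closure,
)

fx = motif_fixtures()

for name in ("FF3", "CY3"):
    g = fx[name]
    print(f"\n{name}: edges {sorted(g.edges)}")
    print(f"{'node':>4} {'E^D':>6} {'E^src':>6} {'E^tgt':>6} "
          f"{'head':>6} {'mid':>6} {'end':>6} {'cyc':>6}")
    for i in sorted(g.nodes):
        e_d = local_directed_closure(g, i)
        e_src, e_tgt = source_target_closure(g, i)
        pats = closure_patterns(g, i)
        cells = [e_d, e_src, e_tgt, *pats]
        row = " ".join("  None" if v is None else f"{v:6.3f}" for v in cells)
        print(f"{i:>4} {row}")
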