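"""Weighted and signed closure on a synthetic trust network.

Users rate each other on a signed scale (think -10 total distrust to +10
total trust).  After normalising by the maximum absolute rating, the
weighted directed closure coefficient E^W,D(i) lies in [-1, 1]: positive
when the triangles around i are on balance trustful, negative when
distrustful cliques dominate.  This script builds a small synthetic rating
network in which most ratings are positive (as balance theory predicts for
real trust networks) and reports the negative-closure census — how many
users sit inside predominantly distrustful cliques.
"""

import numpy as np

from netclosure import (
    DirectedGraph,
    negative_closure_census,
    normalize_weights,
    weighted_directed_closure,
)

rng = np.random.default_rng(7)
n = 60
edges, weights = [], {}
for i in range(n):
    for j in range(n):
        if i != j and rng.random() < 0.08:
            edges.append((i, j))
            # 85% positive ratings, integer scale -10..10
            if rng.random() < 0.85:
                weights[i, j] = float(rng.integers(1, 11))
            else:
                weights[i, j] = -float(rng.integers(1, 11))

g = normalize_weights(DirectedGraph(edges, nodes=range(n), weights=weights))
neg, total = negative_closure_census(g)
print(f"synthetic trust network: {total} users, {g.n_edges} ratings")
print(f"users in predominantly distrustful cliques: {neg}/{total}")

vals = [(i, v) for i in g.nodes
        if (v := weighted_directed_closure(g, i)) is not None]
lo = min(vals, key=lambda t: t[1])
hi = max(vals, key=lambda t: t[1])
print(f"most distrusted-clique user: node {lo[0]} (E^W,D = {lo[1]:+.3f})")
print(f"most trustful-clique user:   node {hi[0]} (E^W,D = {hi[1]:+.3f})")
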