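"""Weighted and signed closure coefficients.

The weighted closure coefficient assigns the potential closing edge its
maximum possible weight (1 after normalisation), so the denominator is a
weight "capacity" built from node strengths:

    E^W(i)   = sum_jk w_ij w_ik w_jk / sum_{j in N(i)} w_ij (s_j - w_ij)
    E^W,D(i) = sum_jk (w_ij+w_ji)(w_ik+w_ki)(w_jk+w_kj)
               / 2 sum_{j in N(i)} (w_ij+w_ji)(s_j - (w_ij+w_ji))

with weights normalised to [0, 1] by the maximum absolute weight and s_j the
strength of j.  On a signed graph (w in [-1, 1]) the strength uses absolute
weights, s_j = sum |w_j.| + sum |w_.j|, and the denominator factors use the
magnitude |w_ij| + |w_ji| so that the denominator stays a positive capacity;
the numerator keeps the raw signs, so E^W,D(i) lies in [-1, 1] and is
negative exactly when negative triangles around i outweigh positive ones.
With 0/1 weights both definitions reduce to their binary counterparts.
"""

from __future__ import annotations

from typing import Optional

from .graph import DirectedGraph, Node

__all__ = [
    "normalize_weights",
    "weighted_closure",
    "weighted_directed_closure",
    "negative_closure_census",
]


def _require_weighted(g: DirectedGraph) -> None:
    if not g.weighted:
        raise ValueError("operation requires a weighted graph")


def normalize_weights(g: DirectedGraph) -> DirectedGraph:
    """Divide every weight by the maximum absolute weight (signs preserved)."""
    _require_weighted(g)
    edges = g.edges
    wmax = max((abs(g.weight(i, j)) for i, j in edges), default=0.0)
    if wmax == 0.0:
        raise ValueError("cannot normalize an all-zero weight set")
    weights = {(i, j): g.weight(i, j) / wmax for i, j in edges}
    times = {(i, j): g.timestamp(i, j) for i, j in edges} if g.timestamped else None
    return DirectedGraph(edges, nodes=g.nodes, weights=weights, timestamps=times)


def _check_normalized(g: DirectedGraph) -> None:
    bad = max((abs(g.weight(i, j)) for i, j in g.edges), default=0.0)
    if bad > 1.0 + 1e-12:
        raise ValueError(
            f"weights must be normalized to [-1, 1] (max |w| = {bad}); "
            "apply normalize_weights first"
        )


def weighted_closure(g: DirectedGraph, i: Node) -> Optional[float]:
    """E^W(i) of a weighted graph treated as undirected.

    The graph may store each undirected edge in one orientation or
    symmetrically (equal weights both ways); the weight of the pair {u, v}
    is read from whichever orientation exists.
    """
    _require_weighted(g)
    _check_normalized(g)

    def w(u, v):
        return g.weight(u, v) if g.has_edge(u, v) else g.weight(v, u)

    nbrs = sorted(g.undirected_neighbors(i), key=str)
    den = 0.0
    for j in nbrs:
        s_j = sum(w(j, u) for u in g.undirected_neighbors(j))
        den += w(i, j) * (s_j - w(i, j))
    if den == 0.0:
        return None
    num = 0.0
    for a, j in enumerate(nbrs):
        for k in nbrs[a + 1:]:
            if g.undirected_edge(j, k):
                num += 2 * w(i, j) * w(i, k) * w(j, k)
    return num / den


def weighted_directed_closure(g: DirectedGraph, i: Node) -> Optional[float]:
    """E^W,D(i) of a weighted (possibly signed) directed graph."""
    _require_weighted(g)
    _check_normalized(g)
    out, inn, nbrs = g.neighbors(i)
    nb = sorted(nbrs, key=str)
    den = 0.0
    for j in nb:
        bij_mag = abs(g.weight(i, j)) + abs(g.weight(j, i))
        den += bij_mag * (g.strength(j) - bij_mag)
    den *= 2.0
    if den == 0.0:
        return None
    num = 0.0
    for a, j in enumerate(nb):
        bij = g.weight(i, j) + g.weight(j, i)
        for k in nb[a + 1:]:
            bik = g.weight(i, k) + g.weight(k, i)
            bjk = g.weight(j, k) + g.weight(k, j)
            num += 2 * bij * bik * bjk
    return num / den


def negative_closure_census(g: DirectedGraph) -> tuple[int, int]:
    """(number of nodes with E^W,D(i) < 0, total node count).

    Nodes with undefined coefficients are never counted as negative.  In a
    trust network a negative coefficient flags a node whose surrounding
    triangles are on balance distrustful; balance theory predicts such nodes
    are rare.
    """
    _require_weighted(g)
    neg = 0
    for i in g.nodes:
        e = weighted_directed_closure(g, i)
        if e is not None and e < 0:
            neg += 1
    return neg, g.n_nodes
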