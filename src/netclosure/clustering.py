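"""Clustering coefficients: undirected, directed, and the four centre-node patterns.

The local clustering coefficient of node i is the fraction of centre-node
open triads at i that are closed: C(i) = T(i) / [d_i(d_i-1)/2] on the
undirected projection.  Its directed analogue counts unidirectional triangle
instances (reciprocated edges decomposed) against the directed open-triad
capacity d_i(d_i-1) - 2 d_i^bi.  The four patterns split the directed count
by the focal node's role: head (both edges out), end (both in), mid
(transitive middleman) and cyc (3-cycles).

Coefficients whose denominator is zero are *undefined* and returned as
``None``; averages map undefined to zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from ._counts import node_counts
from .graph import DirectedGraph, Node

__all__ = [
    "NodeClusteringProfile",
    "local_clustering",
    "global_clustering",
    "local_directed_clustering",
    "global_directed_clustering",
    "clustering_patterns",
    "average_coefficient",
    "clustering_profile",
    "clustering_table",
]


@dataclass(frozen=True)
class NodeClusteringProfile:
    c: Optional[float]       # undirected C(i)
    c_d: Optional[float]     # directed C^D(i)
    c_head: Optional[float]
    c_mid: Optional[float]
    c_end: Optional[float]
    c_cyc: Optional[float]


def _ratio(num: int, den: int) -> Optional[float]:
    return None if den == 0 else num / den


def local_clustering(g: DirectedGraph, i: Node) -> Optional[float]:
    """C(i) on the undirected projection; ``None`` when degree < 2."""
    nc = node_counts(g, i)
    return _ratio(2 * nc.tu, nc.du * (nc.du - 1))


def global_clustering(g: DirectedGraph) -> float:
    """Fraction of undirected open triads closed, over the whole projection."""
    num = den = 0
    for i in g.nodes:
        nc = node_counts(g, i)
        num += 2 * nc.tu
        den += nc.du * (nc.du - 1)
    if den == 0:
        raise ValueError("no open triads in the undirected projection")
    return num / den


def local_directed_clustering(g: DirectedGraph, i: Node) -> Optional[float]:
    """C^D(i) = T^D(i) / [d_i(d_i-1) - 2 d_i^bi]; ``None`` when capacity 0."""
    nc = node_counts(g, i)
    return _ratio(nc.t2, 2 * (nc.d * (nc.d - 1) - 2 * nc.d_bi))


def global_directed_clustering(g: DirectedGraph) -> float:
    """Fraction of directed open-triad instances closed, network-wide."""
    num = den = 0
    for i in g.nodes:
        nc = node_counts(g, i)
        num += nc.t2
        den += 2 * (nc.d * (nc.d - 1) - 2 * nc.d_bi)
    if den == 0:
        raise ValueError("no directed open triads")
    return num / den


def clustering_patterns(
    g: DirectedGraph, i: Node
) -> tuple[Optional[float], Optional[float], Optional[float], Optional[float]]:
    """(c_head, c_mid, c_end, c_cyc) of node ``i``.

    Denominators are the pattern-specific centre-node triad capacities:
    d_out(d_out-1) for head, d_in(d_in-1) for end, and d_in*d_out - d_bi for
    the two mixed patterns.
    """
    nc = node_counts(g, i)
    mixed = nc.d_in * nc.d_out - nc.d_bi
    return (
        _ratio(nc.t_head, nc.d_out * (nc.d_out - 1)),
        _ratio(nc.t_mid, mixed),
        _ratio(nc.t_end, nc.d_in * (nc.d_in - 1)),
        _ratio(nc.t_cyc, mixed),
    )


def average_coefficient(values: Iterable[Optional[float]]) -> float:
    """Mean over all entries with undefined (``None``) mapped to zero."""
    vals = list(values)
    if not vals:
        raise ValueError("empty value list")
    return sum(v for v in vals if v is not None) / len(vals)


def clustering_profile(g: DirectedGraph, i: Node) -> NodeClusteringProfile:
    c_head, c_mid, c_end, c_cyc = clustering_patterns(g, i)
    return NodeClusteringProfile(
        c=local_clustering(g, i),
        c_d=local_directed_clustering(g, i),
        c_head=c_head, c_mid=c_mid, c_end=c_end, c_cyc=c_cyc,
    )


def clustering_table(g: DirectedGraph) -> pd.DataFrame:
    """Per-node clustering profile as a DataFrame (undefined -> NaN)."""
    rows = []
    for i in g.nodes:
        p = clustering_profile(g, i)
        rows.append({"node": i, "c": p.c, "c_d": p.c_d, "c_head": p.c_head,
                     "c_mid": p.c_mid, "c_end": p.c_end, "c_cyc": p.c_cyc})
    return pd.DataFrame(rows)
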