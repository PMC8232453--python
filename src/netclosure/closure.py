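"""Closure coefficients: triangle formation measured from the end-node.

Where the clustering coefficient asks how often the two neighbours of a focal
node are themselves connected, the closure coefficient asks how often a
length-2 path *starting* at the focal node is closed by an edge incident to
that node.  The local closure coefficient of node i is

    E(i) = 2 T(i) / sum_{j in N(i)} (d_j - 1),

and its directed analogue E^D(i) divides twice the number of unidirectional
triangle instances containing i by twice the number of directed open triads
with i as end-node, OTE^D(i) = sum_j (a_ij + a_ji)(d_j - a_ij - a_ji).
Because the closing edge of an end-node open triad is incident to the focal
node, its direction splits E^D into a source part (closing edge leaves i) and
a target part (closing edge enters i) with E^src(i) + E^tgt(i) = 2 E^D(i),
and the transitive taxonomy yields four pattern coefficients (head/mid/end/
cyc).  On a directed Erdos-Renyi G(n, p) graph, E[E^D(i)] = p.

Undefined coefficients (zero denominator) are ``None``; averages treat them
as zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from ._counts import node_counts
from .clustering import average_coefficient
from .graph import DirectedGraph, Node

__all__ = [
    "NodeClosureProfile",
    "local_closure",
    "global_closure",
    "local_directed_closure",
    "source_target_closure",
    "closure_patterns",
    "average_directed_closure",
    "global_directed_closure",
    "closure_profile",
    "closure_table",
]


@dataclass(frozen=True)
class NodeClosureProfile:
    e: Optional[float]       # undirected E(i)
    e_d: Optional[float]     # directed E^D(i)
    e_src: Optional[float]
    e_tgt: Optional[float]
    e_head: Optional[float]
    e_mid: Optional[float]
    e_end: Optional[float]
    e_cyc: Optional[float]


def _ratio(num: int, den: int) -> Optional[float]:
    return None if den == 0 else num / den


def local_closure(g: DirectedGraph, i: Node) -> Optional[float]:
    """E(i) = 2T(i)/OTE(i) on the undirected projection; ``None`` if OTE=0."""
    nc = node_counts(g, i)
    return _ratio(2 * nc.tu, nc.ote_u)


def global_closure(g: DirectedGraph) -> float:
    """Network-level closure on the projection (equals global clustering)."""
    num = den = 0
    for i in g.nodes:
        nc = node_counts(g, i)
        num += 2 * nc.tu
        den += nc.ote_u
    if den == 0:
        raise ValueError("no open triads in the undirected projection")
    return num / den


def local_directed_closure(g: DirectedGraph, i: Node) -> Optional[float]:
    """E^D(i) = 2T^D(i) / 2OTE^D(i); ``None`` when i's neighbours connect
    only to i (OTE^D(i) = 0)."""
    nc = node_counts(g, i)
    return _ratio(nc.t2, 2 * nc.ote_total)


def source_target_closure(
    g: DirectedGraph, i: Node
) -> tuple[Optional[float], Optional[float]]:
    """(E^src(i), E^tgt(i)) — closure split by closing-edge direction.

    Both share the denominator OTE^D(i) (the closing edge is constrained to
    a single direction, so the capacity is not doubled), which gives the
    identity E^src(i) + E^tgt(i) = 2 E^D(i).
    """
    nc = node_counts(g, i)
    return _ratio(nc.t_src, nc.ote_total), _ratio(nc.t_tgt, nc.ote_total)


def closure_patterns(
    g: DirectedGraph, i: Node
) -> tuple[Optional[float], Optional[float], Optional[float], Optional[float]]:
    """(e_head, e_mid, e_end, e_cyc) of node ``i``.

    Each pattern divides twice its triangle count by the capacity of the two
    end-node open-triad types that can close into it:

        e_head: OTE(oo) + OTE(oi)   e_end: OTE(ii) + OTE(io)
        e_mid:  OTE(oi) + OTE(io)   e_cyc: OTE(oo) + OTE(ii)

    where the two letters give the directions of the (i, j) and (j, k) edges.
    """
    nc = node_counts(g, i)
    return (
        _ratio(2 * nc.t_head, nc.ote_oo + nc.ote_oi),
        _ratio(2 * nc.t_mid, nc.ote_oi + nc.ote_io),
        _ratio(2 * nc.t_end, nc.ote_ii + nc.ote_io),
        _ratio(2 * nc.t_cyc, nc.ote_oo + nc.ote_ii),
    )


def average_directed_closure(g: DirectedGraph) -> float:
    """Mean of E^D(i) over all nodes, undefined treated as zero."""
    return average_coefficient(local_directed_closure(g, i) for i in g.nodes)


def global_directed_closure(g: DirectedGraph) -> float:
    """Network-level directed closure; equals global directed clustering."""
    num = den = 0
    for i in g.nodes:
        nc = node_counts(g, i)
        num += nc.t2
        den += 2 * nc.ote_total
    if den == 0:
        raise ValueError("no directed open triads")
    return num / den


def closure_profile(g: DirectedGraph, i: Node) -> NodeClosureProfile:
    e_src, e_tgt = source_target_closure(g, i)
    e_head, e_mid, e_end, e_cyc = closure_patterns(g, i)
    return NodeClosureProfile(
        e=local_closure(g, i),
        e_d=local_directed_closure(g, i),
        e_src=e_src, e_tgt=e_tgt,
        e_head=e_head, e_mid=e_mid, e_end=e_end, e_cyc=e_cyc,
    )


def closure_table(g: DirectedGraph) -> pd.DataFrame:
    """Per-node closure profile as a DataFrame (undefined -> NaN)."""
    rows = []
    for i in g.nodes:
        p = closure_profile(g, i)
        rows.append({"node": i, "e": p.e, "e_d": p.e_d, "e_src": p.e_src,
                     "e_tgt": p.e_tgt, "e_head": p.e_head, "e_mid": p.e_mid,
                     "e_end": p.e_end, "e_cyc": p.e_cyc})
    return pd.DataFrame(rows)
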