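"""Brute-force enumeration of directed triads and triangles — the test oracle.

Every fast coefficient in this package is a ratio of counts that this module
recomputes by exhaustive iteration over node pairs, decomposing each
reciprocated edge into its two unidirectional components and classifying each
resulting *instance* by explicit case analysis.  Deliberately naive (O(n^2)
per node): the point is that it is independent of the neighbourhood algebra
used by the fast path, so agreement between the two is meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

from .graph import DirectedGraph, Node

__all__ = ["TriadCounts", "TriangleCounts", "enumerate_triads", "enumerate_triangles"]

OUT, IN = 0, 1  # direction of an edge instance relative to its first node


@dataclass(frozen=True)
class TriadCounts:
    """Open-triad instance counts at a focal node.

    ``ote_*`` fields count triads with the focal node as end-node, keyed by
    the directions of the (i, j) and (j, k) edges (o: pointing away from the
    earlier node, i: pointing back).  ``otc_*`` fields count centre-node
    triads keyed by the directions of the two edges at the focal node.
    """

    ote_oo: int
    ote_oi: int
    ote_io: int
    ote_ii: int
    ote_total: int
    otc_oo: int
    otc_ii: int
    otc_oi: int
    otc_total: int


@dataclass(frozen=True)
class TriangleCounts:
    """Directed-triangle instance counts at a focal node.

    ``t_d`` is the total number of unidirectional triangle instances
    containing the node; ``t_src``/``t_tgt`` count end-node-perspective views
    split by whether the closing edge leaves or enters the node (so
    ``t_src + t_tgt = 2 t_d``); the four pattern counts partition ``t_d`` by
    the node's position in the triangle's length-2 path.
    """

    t_d: int
    t_src: int
    t_tgt: int
    t_head: int
    t_mid: int
    t_end: int
    t_cyc: int


def _slot_instances(g: DirectedGraph, u: Node, v: Node) -> list[int]:
    """Unidirectional edge instances in the u-v slot, as directions rel. u."""
    inst = []
    if g.has_edge(u, v):
        inst.append(OUT)
    if g.has_edge(v, u):
        inst.append(IN)
    return inst


def enumerate_triads(g: DirectedGraph, i: Node) -> TriadCounts:
    """Count open-triad instances at ``i`` by exhaustive pair iteration."""
    g._require_node(i)
    others = [v for v in g.nodes if v != i]
    ote = {(OUT, OUT): 0, (OUT, IN): 0, (IN, OUT): 0, (IN, IN): 0}
    otc = {(OUT, OUT): 0, (IN, IN): 0, "mixed": 0}
    for j in others:
        for k in others:
            if k == j:
                continue
            # end-node triads: an (i-j) instance plus a (j-k) instance
            for e1 in _slot_instances(g, i, j):
                for e2 in _slot_instances(g, j, k):
                    ote[e1, e2] += 1
    seen = set()
    for j in others:
        for k in others:
            if k == j or (k, j) in seen:
                continue
            seen.add((j, k))
            # centre-node triads: an (i-j) instance plus an (i-k) instance
            for e1 in _slot_instances(g, i, j):
                for e2 in _slot_instances(g, i, k):
                    if e1 == e2 == OUT:
                        otc[OUT, OUT] += 1
                    elif e1 == e2 == IN:
                        otc[IN, IN] += 1
                    else:
                        otc["mixed"] += 1
    return TriadCounts(
        ote_oo=ote[OUT, OUT], ote_oi=ote[OUT, IN],
        ote_io=ote[IN, OUT], ote_ii=ote[IN, IN],
        ote_total=sum(ote.values()),
        otc_oo=otc[OUT, OUT], otc_ii=otc[IN, IN], otc_oi=otc["mixed"],
        otc_total=sum(otc.values()),
    )


def enumerate_triangles(g: DirectedGraph, i: Node) -> TriangleCounts:
    """Count directed-triangle instances at ``i`` by exhaustive enumeration."""
    g._require_node(i)
    others = [v for v in g.nodes if v != i]
    t_d = t_src = t_tgt = 0
    t_head = t_mid = t_end = t_cyc = 0
    for a, j in enumerate(others):
        for k in others[a + 1:]:
            for e1 in _slot_instances(g, i, j):     # i-j slot
                for e2 in _slot_instances(g, i, k):  # i-k slot
                    for e3 in _slot_instances(g, j, k):  # j-k slot
                        t_d += 1
                        # end-node views: each incident edge in turn is the
                        # closing edge; outgoing closes a source view
                        t_src += (e1 == OUT) + (e2 == OUT)
                        t_tgt += (e1 == IN) + (e2 == IN)
                        if e1 == OUT and e2 == OUT:
                            t_head += 1
                        elif e1 == IN and e2 == IN:
                            t_end += 1
                        elif e1 == IN and e2 == OUT:
                            # path j -> i -> k; cyclic iff the third edge
                            # returns k -> j
                            t_cyc += 1 if e3 == IN else 0
                            t_mid += 1 if e3 == OUT else 0
                        else:
                            # path k -> i -> j; cyclic iff j -> k
                            t_cyc += 1 if e3 == OUT else 0
                            t_mid += 1 if e3 == IN else 0
    return TriangleCounts(
        t_d=t_d, t_src=t_src, t_tgt=t_tgt,
        t_head=t_head, t_mid=t_mid, t_end=t_end, t_cyc=t_cyc,
    )
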