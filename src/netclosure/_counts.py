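"""Fast per-node integer counts of directed triads and triangles.

All coefficients in :mod:`netclosure.clustering` and :mod:`netclosure.closure`
are ratios of the integers computed here.  Counts follow the bidirectional
decomposition convention: a reciprocated edge is two unidirectional edges, so
a triangle with two bidirectional edges contributes four unidirectional
triangle instances, and so on.  Everything is computed from the neighbourhood
of the focal node and the degrees of its neighbours — O(k^2) per node with
k the node degree — and kept as exact integers; division happens only in the
public coefficient functions.
"""

from __future__ import annotations

from dataclasses import dataclass

from .graph import DirectedGraph, Node

__all__ = ["NodeCounts", "node_counts"]


@dataclass(frozen=True)
class NodeCounts:
    # degrees
    d_out: int
    d_in: int
    d: int
    d_bi: int
    # directed triangle instance counts (after bidirectional decomposition)
    t2: int          # 2*T^D(i) = sum_{j!=k} (a_ij+a_ji)(a_ik+a_ki)(a_jk+a_kj)
    t_src: int       # closing-edge-out instances, end-node perspective
    t_tgt: int       # closing-edge-in instances
    t_head: int      # transitive patterns; t_head+t_mid+t_end+t_cyc = t2/2
    t_mid: int
    t_end: int
    t_cyc: int
    # open triads with i as END-node, by (i-j, j-k) edge directions
    ote_oo: int      # i->j, j->k
    ote_oi: int      # i->j, k->j
    ote_io: int      # j->i, j->k
    ote_ii: int      # j->i, k->j
    ote_total: int   # OTE^D(i)
    # open triads with i as CENTRE-node
    otc_oo: int      # i->j, i->k
    otc_ii: int      # j->i, k->i
    otc_oi: int      # mixed
    otc_total: int   # OTC^D(i) = (d(d-1) - 2 d_bi)/2
    # undirected projection
    du: int          # degree in the projection
    tu: int          # T(i): triangles containing i in the projection
    ote_u: int       # OTE(i) = sum_{j in N(i)} (d_j - 1), projected degrees

    @property
    def t_d(self) -> int:
        """T^D(i): number of unidirectional triangle instances containing i."""
        return self.t2 // 2


def node_counts(g: DirectedGraph, i: Node) -> NodeCounts:
    """All triad/triangle counts at node ``i`` via neighbourhood iteration."""
    out, inn = g._sets(i)
    nbrs = out | inn
    d_out, d_in = len(out), len(inn)
    d_bi = len(out & inn)
    d = d_out + d_in

    # open triads from neighbour degrees
    ote_oo = ote_oi = ote_io = ote_ii = 0
    ote_u = 0
    succ = {}
    for j in nbrs:
        j_out, j_in = g._sets(j)
        succ[j] = j_out
        aij = 1 if j in out else 0
        aji = 1 if j in inn else 0
        ote_oo += aij * (len(j_out) - aji)
        ote_oi += aij * (len(j_in) - aij)
        ote_io += aji * (len(j_out) - aji)
        ote_ii += aji * (len(j_in) - aij)
        ote_u += len(j_out | j_in) - 1
    ote_total = ote_oo + ote_oi + ote_io + ote_ii

    otc_oo = d_out * (d_out - 1) // 2
    otc_ii = d_in * (d_in - 1) // 2
    otc_oi = d_out * d_in - d_bi
    otc_total = otc_oo + otc_ii + otc_oi

    # triangle instances: ordered pairs (j, k) of distinct neighbours
    nb = sorted(nbrs, key=str)
    t2 = t_src = t_tgt = 0
    th2 = te2 = t_mid = t_cyc = 0
    tu = 0
    for a, j in enumerate(nb):
        aij = 1 if j in out else 0
        aji = 1 if j in inn else 0
        bij = aij + aji
        succ_j = succ[j]
        for b, k in enumerate(nb):
            if a == b:
                continue
            aik = 1 if k in out else 0
            aki = 1 if k in inn else 0
            bik = aik + aki
            ajk = 1 if k in succ_j else 0
            akj = 1 if j in succ[k] else 0
            bjk = ajk + akj
            t2 += bij * bik * bjk
            t_src += bij * bjk * aik
            t_tgt += bij * bjk * aki
            th2 += aij * aik * bjk
            te2 += aji * aki * bjk
            t_mid += aji * aik * ajk
            t_cyc += aij * ajk * aki
            if a < b and bjk:
                tu += 1
    assert t2 % 2 == 0 and th2 % 2 == 0 and te2 % 2 == 0

    return NodeCounts(
        d_out=d_out, d_in=d_in, d=d, d_bi=d_bi,
        t2=t2, t_src=t_src, t_tgt=t_tgt,
        t_head=th2 // 2, t_mid=t_mid, t_end=te2 // 2, t_cyc=t_cyc,
        ote_oo=ote_oo, ote_oi=ote_oi, ote_io=ote_io, ote_ii=ote_ii,
        ote_total=ote_total,
        otc_oo=otc_oo, otc_ii=otc_ii, otc_oi=otc_oi, otc_total=otc_total,
        du=len(nbrs), tu=tu, ote_u=ote_u,
    )
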