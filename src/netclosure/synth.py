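"""Seeded random-graph generators and canonical motif fixtures.

The random model is the directed Erdos-Renyi G(n, p): every ordered pair
(i, j), i != j, carries an edge independently with probability p.  This is
the setting in which the expected local directed closure coefficient equals
p, which the test suite checks.  Weighted variants draw unsigned weights
uniformly on (0, 1] and signed weights uniformly on [-1, 1] excluding 0.

The motif fixtures are the small graphs used throughout the tests: the
feed-forward triangle FF3, the 3-cycle CY3, a bidirectional triad BI3, the
eight labelled direction patterns of a directed triangle, the four end-node
open-triad types, and a small undirected family.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .graph import DirectedGraph

__all__ = ["random_directed_gnp", "random_weighted_gnp", "motif_fixtures"]


def random_directed_gnp(
    n: int, p: float, seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> DirectedGraph:
    """Directed G(n, p): each ordered pair is an edge with probability p."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if rng is None:
        rng = np.random.default_rng(seed)
    mask = rng.random((n, n)) < p
    np.fill_diagonal(mask, False)
    src, dst = np.nonzero(mask)
    edges = [(int(i), int(j)) for i, j in zip(src, dst)]
    return DirectedGraph(edges, nodes=range(n))


def random_weighted_gnp(
    n: int, p: float, seed: Optional[int] = None, signed: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> DirectedGraph:
    """Weighted directed G(n, p); weights uniform on (0,1], or on [-1,1]\\{0}
    when ``signed``."""
    if rng is None:
        rng = np.random.default_rng(seed)
    g = random_directed_gnp(n, p, rng=rng)
    edges = g.edges
    mags = 1.0 - rng.random(len(edges))  # (0, 1]
    if signed:
        signs = np.where(rng.random(len(edges)) < 0.5, -1.0, 1.0)
        mags = mags * signs
    weights = {e: float(w) for e, w in zip(edges, mags)}
    return DirectedGraph(edges, nodes=range(n), weights=weights)


def _g(*edges) -> DirectedGraph:
    return DirectedGraph(edges)


def motif_fixtures() -> dict[str, DirectedGraph]:
    """Canonical small directed graphs, keyed by name.

    Triangle fixtures ``TRI-xyz`` are on nodes 1, 2, 3 with focal node 1;
    x, y, z in {o, i} give the directions of the 1-2, 1-3 and 2-3 edges
    (o: away from the lower-numbered node).  Open-triad fixtures ``OT-xy``
    have edges in the 1-2 and 2-3 slots only.
    """
    fx = {
        "FF3": _g((1, 2), (2, 3), (1, 3)),
        "CY3": _g((1, 2), (2, 3), (3, 1)),
        "BI3": _g((1, 2), (2, 1), (1, 3)),
        "U-TRIANGLE": _g((1, 2), (2, 3), (1, 3)),
        "U-PATH": _g(("a", "b"), ("b", "c")),
        "U-STAR": _g(("c", "l1"), ("c", "l2"), ("c", "l3")),
    }
    for x in "oi":
        for y in "oi":
            e12 = (1, 2) if x == "o" else (2, 1)
            e13 = (1, 3) if y == "o" else (3, 1)
            for z in "oi":
                e23 = (2, 3) if z == "o" else (3, 2)
                fx[f"TRI-{x}{y}{z}"] = _g(e12, e13, e23)
    for x in "oi":
        for y in "oi":
            e12 = (1, 2) if x == "o" else (2, 1)
            e23 = (2, 3) if y == "o" else (3, 2)
            fx[f"OT-{x}{y}"] = DirectedGraph([e12, e23], nodes=[1, 2, 3])
    return fx
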