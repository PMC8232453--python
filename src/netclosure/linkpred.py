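"""Neighbourhood-based link prediction for directed networks.

Baseline indices score an ordered candidate pair (s, t) from the common
neighbourhood N_out(s) & N_in(t):

    DiCN(s, t) = |N_out(s) & N_in(t)|
    DiAA(s, t) = sum_{u in N_out(s) & N_in(t)} 1 / ln |N(u)|
    DiRA(s, t) = sum_{u in N_out(s) & N_in(t)} 1 / |N(u)|

The closure-closeness indices weight the common-neighbour count by how prone
s is to emit closing edges and t to receive them:

    CCI(s, t)  = |N_out(s) & N_in(t)| * (E^src(s) + E^tgt(t))
    ECCI(s, t) = |N(s) & N(t)|        * (E^src(s) + E^tgt(t))

Evaluation follows a hold-out protocol: the edge set is split 50/50 (by
timestamp when available, uniformly at random otherwise, repeated), indices
are computed on the old graph, every non-edge ordered pair over its nodes is
scored, and the ranking is summarised by PR-AUC (non-interpolated average
precision).  On networks with more than ``sample_threshold`` nodes, 3,000
connected nodes are sampled and candidates restricted to pairs among them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .closure import source_target_closure
from .graph import DirectedGraph, Node

__all__ = [
    "METHODS",
    "ScoredPair",
    "EvalProtocol",
    "split_old_new",
    "ClosureCache",
    "score_pair",
    "candidate_pairs",
    "pr_auc",
    "evaluate",
]

METHODS = ("DiCN", "DiAA", "DiRA", "CCI", "ECCI")


@dataclass(frozen=True)
class ScoredPair:
    source: Node
    target: Node
    score: float
    label: bool  # True iff the pair appears among the future edges


@dataclass(frozen=True)
class EvalProtocol:
    """Hold-out evaluation settings.

    ``split_fraction`` of the edges form the old graph; non-temporal splits
    are repeated ``repeats`` times; networks larger than
    ``sample_threshold`` nodes are reduced to ``sample_size`` connected
    nodes per repeat.
    """

    split_fraction: float = 0.5
    repeats: int = 10
    sample_size: int = 3000
    sample_threshold: int = 10000
    temporal: bool = False
    seed: Optional[int] = None

    def __post_init__(self):
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must be in (0, 1)")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


def split_old_new(
    g: DirectedGraph,
    protocol: EvalProtocol,
    rng: Optional[np.random.Generator] = None,
) -> tuple[DirectedGraph, set[tuple[Node, Node]]]:
    """Split into an old graph and the set of future edges among its nodes.

    Temporal splits take the earliest ``split_fraction`` of edges (ties
    broken by input order); random splits permute the edge list with ``rng``.
    Future edges with an endpoint outside the old graph's node set are
    discarded.
    """
    edges = g.edges
    if protocol.temporal:
        if not g.timestamped:
            raise ValueError("temporal split requires edge timestamps")
        order = sorted(range(len(edges)), key=lambda k: (g.timestamp(*edges[k]), k))
        edges = [edges[k] for k in order]
    else:
        if rng is None:
            rng = np.random.default_rng(protocol.seed)
        edges = [edges[k] for k in rng.permutation(len(edges))]
    n_old = int(math.floor(protocol.split_fraction * len(edges)))
    e_old, e_future = edges[:n_old], edges[n_old:]
    if g.weighted:
        weights = {e: g.weight(*e) for e in e_old}
    else:
        weights = None
    g_old = DirectedGraph(e_old, weights=weights)
    v_star = set(g_old.nodes)
    e_new = {(s, t) for s, t in e_future
             if s in v_star and t in v_star and not g_old.has_edge(s, t)}
    return g_old, e_new


class ClosureCache:
    """Lazy per-node (E^src, E^tgt) cache on a fixed graph; undefined -> 0."""

    def __init__(self, g: DirectedGraph):
        self._g = g
        self._vals: dict[Node, tuple[float, float]] = {}

    def __call__(self, i: Node) -> tuple[float, float]:
        if i not in self._vals:
            e_src, e_tgt = source_target_closure(self._g, i)
            self._vals[i] = (e_src or 0.0, e_tgt or 0.0)
        return self._vals[i]


def score_pair(
    g_old: DirectedGraph,
    s: Node,
    t: Node,
    method: str,
    closure_cache: Optional[ClosureCache] = None,
) -> float:
    """Similarity score of the ordered pair (s, t) under one index."""
    if s == t:
        raise ValueError("self-pairs are not scored")
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    s_out, _, s_all = g_old.neighbors(s)
    _, t_in, t_all = g_old.neighbors(t)
    common = s_out & t_in
    if method == "DiCN":
        return float(len(common))
    if method == "DiAA":
        # every u here neighbours both s and t, so |N(u)| >= 2 and the log
        # is bounded away from zero
        return sum(1.0 / math.log(len(g_old.undirected_neighbors(u))) for u in common)
    if method == "DiRA":
        return sum(1.0 / len(g_old.undirected_neighbors(u)) for u in common)
    if closure_cache is None:
        closure_cache = ClosureCache(g_old)
    coef = closure_cache(s)[0] + closure_cache(t)[1]
    if method == "CCI":
        return len(common) * coef
    return len(s_all & t_all) * coef  # ECCI


def candidate_pairs(
    g_old: DirectedGraph, nodes: Optional[Sequence[Node]] = None
) -> Iterator[tuple[Node, Node]]:
    """All ordered non-self pairs over the node set that are not old edges."""
    if nodes is None:
        nodes = g_old.nodes
    for s in nodes:
        for t in nodes:
            if s != t and not g_old.has_edge(s, t):
                yield s, t


def pr_auc(scored: Iterable[ScoredPair]) -> float:
    """Non-interpolated average precision of the descending-score ranking.

    Ties are broken by stable input order.  Equals the mean, over positives,
    of the precision at each positive's rank.
    """
    ranked = sorted(scored, key=lambda sp: -sp.score)
    n_pos = 0
    ap = 0.0
    for rank, sp in enumerate(ranked, start=1):
        if sp.label:
            n_pos += 1
            ap += n_pos / rank
    if n_pos == 0:
        raise ValueError("average precision undefined without positive labels")
    return ap / n_pos


def _run_once(
    g_old: DirectedGraph,
    e_new: set[tuple[Node, Node]],
    methods: Sequence[str],
    nodes: Optional[Sequence[Node]] = None,
) -> dict[str, float]:
    cache = ClosureCache(g_old)
    pairs = list(candidate_pairs(g_old, nodes))
    out = {}
    for m in methods:
        scored = [
            ScoredPair(s, t, score_pair(g_old, s, t, m, cache), (s, t) in e_new)
            for s, t in pairs
        ]
        out[m] = pr_auc(scored)
    return out


def evaluate(
    g: DirectedGraph,
    protocol: EvalProtocol,
    methods: Sequence[str] = METHODS,
) -> pd.DataFrame:
    """Mean PR-AUC per method under the hold-out protocol.

    Returns a DataFrame with one row per repeat plus per-method columns; the
    ``mean`` row aggregates.  Temporal evaluation on small networks is a
    single deterministic run; all randomness flows from ``protocol.seed``.
    """
    rng = np.random.default_rng(protocol.seed)
    sample = g.n_nodes > protocol.sample_threshold
    if protocol.temporal and not sample:
        repeats = 1
    else:
        repeats = protocol.repeats
    rows = []
    for r in range(repeats):
        g_old, e_new = split_old_new(g, protocol, rng=rng)
        nodes = None
        if sample:
            connected = [v for v in g_old.nodes
                         if g_old.degrees(v).total_degree >= 1]
            k = min(protocol.sample_size, len(connected))
            idx = rng.choice(len(connected), size=k, replace=False)
            nodes = [connected[int(x)] for x in idx]
            e_new = {(s, t) for s, t in e_new if s in set(nodes) and t in set(nodes)}
        if not e_new:
            continue
        rows.append({"repeat": r, **_run_once(g_old, e_new, methods, nodes)})
    if not rows:
        raise ValueError("no repeat produced future edges to predict")
    df = pd.DataFrame(rows).set_index("repeat")
    df.loc["mean"] = df.mean()
    return df
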