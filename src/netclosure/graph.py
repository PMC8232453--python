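"""Directed-graph data model and plain-text edge-list I/O.

The :class:`DirectedGraph` is a thin immutable-ish wrapper around a
:class:`networkx.DiGraph` that enforces the conventions every metric in this
package assumes: a simple digraph (no self-loops, no parallel edges), with
optional real-valued edge weights (which may be signed) and optional
timestamps.  Node identifiers are opaque hashables; the edge-list loader keeps
them as the verbatim strings found in the file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Hashable, Iterable, Iterator, Mapping, Optional, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

Node = Hashable
Edge = tuple[Node, Node]

__all__ = [
    "DirectedGraph",
    "DegreeRecord",
    "MalformedLineError",
    "load_edge_list",
    "write_edge_list",
]


class MalformedLineError(ValueError):
    """Raised when an edge-list line cannot be parsed; carries the line number."""

    def __init__(self, lineno: int, line: str, reason: str):
        self.lineno = lineno
        super().__init__(f"line {lineno}: {reason!s} ({line!r})")


@dataclass(frozen=True)
class DegreeRecord:
    """Degree bundle of one node in a simple digraph.

    ``d = d_out + d_in`` is the total degree used throughout the directed
    coefficients; ``d_bi`` counts neighbours connected by a reciprocated
    (bidirectional) edge; ``strength`` is the sum of incident edge weights
    (absolute values on signed graphs), equal to ``d`` on unweighted graphs.
    """

    out_degree: int
    in_degree: int
    total_degree: int
    bidirectional_degree: int
    strength: float


class DirectedGraph:
    """A simple directed graph with optional signed weights and timestamps."""

    def __init__(
        self,
        edges: Iterable[Edge] = (),
        nodes: Iterable[Node] = (),
        weights: Optional[Mapping[Edge, float]] = None,
        timestamps: Optional[Mapping[Edge, float]] = None,
    ):
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        n_loops = 0
        for e in edges:
            i, j = e
            if i == j:
                n_loops += 1
                g.add_node(i)
                continue
            attrs = {}
            if weights is not None:
                if (i, j) not in weights:
                    raise ValueError(f"edge {e} has no weight but weights were given")
                w = float(weights[i, j])
                if w == 0.0:
                    # a zero-weight edge is indistinguishable from absence in
                    # every formula; drop it at construction
                    g.add_node(i), g.add_node(j)
                    continue
                attrs["weight"] = w
            if timestamps is not None:
                if (i, j) not in timestamps:
                    raise ValueError(f"edge {e} has no timestamp but timestamps were given")
                attrs["time"] = float(timestamps[i, j])
            g.add_edge(i, j, **attrs)
        if n_loops:
            logger.info("dropped %d self-loop(s) at construction", n_loops)
        self._g = g
        self.weighted = weights is not None
        self.timestamped = timestamps is not None
        self._adj_cache: dict[Node, tuple[set[Node], set[Node]]] = {}

    def _sets(self, i: Node) -> tuple[set[Node], set[Node]]:
        """Cached (successor set, predecessor set); callers must not mutate."""
        try:
            return self._adj_cache[i]
        except KeyError:
            pair = (set(self._g.successors(i)), set(self._g.predecessors(i)))
            self._adj_cache[i] = pair
            return pair

    # -- basic accessors ---------------------------------------------------

    @property
    def nodes(self) -> Sequence[Node]:
        return list(self._g.nodes)

    @property
    def edges(self) -> list[Edge]:
        return list(self._g.edges)

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def __contains__(self, i: Node) -> bool:
        return i in self._g

    def has_edge(self, i: Node, j: Node) -> bool:
        return self._g.has_edge(i, j)

    def weight(self, i: Node, j: Node, default: float = 0.0) -> float:
        """Weight of edge i->j (1.0 on unweighted graphs), or ``default``."""
        try:
            d = self._g[i][j]
        except KeyError:
            return default
        return d.get("weight", 1.0)

    def timestamp(self, i: Node, j: Node) -> float:
        return self._g[i][j]["time"]

    @property
    def signed(self) -> bool:
        return self.weighted and any(
            d.get("weight", 1.0) < 0 for _, _, d in self._g.edges(data=True)
        )

    def _require_node(self, i: Node) -> None:
        if i not in self._g:
            raise KeyError(f"unknown node {i!r}")

    # -- neighbourhoods ----------------------------------------------------

    def out_neighbors(self, i: Node) -> set[Node]:
        self._require_node(i)
        return set(self._sets(i)[0])

    def in_neighbors(self, i: Node) -> set[Node]:
        self._require_node(i)
        return set(self._sets(i)[1])

    def neighbors(self, i: Node) -> tuple[set[Node], set[Node], set[Node]]:
        """``(N_out(i), N_in(i), N(i))`` with ``N(i) = N_out(i) | N_in(i)``."""
        out, inn = self.out_neighbors(i), self.in_neighbors(i)
        return out, inn, out | inn

    def adj(self, i: Node, j: Node) -> int:
        """a_ij: 1 if the edge i->j exists, else 0."""
        return 1 if self._g.has_edge(i, j) else 0

    def mutual(self, i: Node, j: Node) -> int:
        """a_ij + a_ji in {0, 1, 2}: the multiplicity of the i-j slot after
        decomposing a bidirectional edge into two unidirectional ones."""
        return self.adj(i, j) + self.adj(j, i)

    # -- degrees and summary statistics -------------------------------------

    def degrees(self, i: Node) -> DegreeRecord:
        self._require_node(i)
        out, inn = self.out_neighbors(i), self.in_neighbors(i)
        d_out, d_in = len(out), len(inn)
        d_bi = len(out & inn)
        if self.weighted:
            s = sum(abs(self.weight(i, j)) for j in out) + sum(
                abs(self.weight(j, i)) for j in inn
            )
        else:
            s = float(d_out + d_in)
        return DegreeRecord(d_out, d_in, d_out + d_in, d_bi, s)

    def strength(self, i: Node) -> float:
        """s_i: sum of incident weights, absolute values on signed graphs."""
        return self.degrees(i).strength

    def reciprocity(self) -> float:
        """Fraction of edges whose reverse edge also exists."""
        m = self.n_edges
        if m == 0:
            raise ValueError("reciprocity undefined on an empty edge set")
        return sum(1 for i, j in self._g.edges if self._g.has_edge(j, i)) / m

    def average_degree(self) -> float:
        """|E|/|V| (the edge-per-node convention used in the summary tables)."""
        if self.n_nodes == 0:
            raise ValueError("average degree undefined on an empty graph")
        return self.n_edges / self.n_nodes

    # -- derived graphs ------------------------------------------------------

    def symmetrized(self) -> "DirectedGraph":
        """Add every reverse edge (weights copied); drops timestamps."""
        edges = set(self._g.edges)
        edges |= {(j, i) for i, j in self._g.edges}
        weights = None
        if self.weighted:
            weights = {}
            for i, j in edges:
                w = self.weight(i, j) if self._g.has_edge(i, j) else self.weight(j, i)
                weights[i, j] = w
        return DirectedGraph(sorted(edges, key=str), nodes=self.nodes, weights=weights)

    def undirected_neighbors(self, i: Node) -> set[Node]:
        out, inn = self.out_neighbors(i), self.in_neighbors(i)
        return out | inn

    def undirected_edge(self, i: Node, j: Node) -> bool:
        return self._g.has_edge(i, j) or self._g.has_edge(j, i)

    def to_networkx(self) -> nx.DiGraph:
        return self._g.copy()


def load_edge_list(
    path,
    delimiter: Optional[str] = None,
    weighted: bool = False,
    timestamped: bool = False,
    signed: bool = False,
) -> DirectedGraph:
    """Read a plain-text edge list ``src dst [weight] [timestamp]``.

    Lines starting with '#' or '%' and blank lines are skipped.  Self-loops
    are dropped (logged); duplicate ordered pairs collapse to one edge,
    keeping the last weight/timestamp seen (logged).  Node identifiers are
    kept as verbatim strings.
    """
    edges: dict[Edge, tuple[Optional[float], Optional[float]]] = {}
    n_loops = n_dups = 0
    min_fields = 2 + (1 if weighted else 0) + (1 if timestamped else 0)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line[0] in "#%":
                continue
            fields = line.split(delimiter)
            if len(fields) < min_fields:
                raise MalformedLineError(
                    lineno, line, f"expected at least {min_fields} fields"
                )
            i, j = fields[0], fields[1]
            w = t = None
            k = 2
            if weighted:
                try:
                    w = float(fields[k])
                except ValueError as exc:
                    raise MalformedLineError(lineno, line, f"bad weight: {exc}") from None
                if w < 0 and not signed:
                    raise MalformedLineError(
                        lineno, line, "negative weight on an unsigned graph"
                    )
                k += 1
            if timestamped:
                try:
                    t = float(fields[k])
                except ValueError as exc:
                    raise MalformedLineError(lineno, line, f"bad timestamp: {exc}") from None
            if i == j:
                n_loops += 1
                continue
            if (i, j) in edges:
                n_dups += 1
            edges[i, j] = (w, t)
    if n_loops:
        logger.info("%s: dropped %d self-loop(s)", path, n_loops)
    if n_dups:
        logger.info("%s: collapsed %d duplicate edge(s), keeping last", path, n_dups)
    weights = {e: wt[0] for e, wt in edges.items()} if weighted else None
    times = {e: wt[1] for e, wt in edges.items()} if timestamped else None
    return DirectedGraph(edges.keys(), weights=weights, timestamps=times)


def write_edge_list(g: DirectedGraph, path, delimiter: str = " ") -> None:
    """Write the graph in the same ``src dst [weight] [timestamp]`` format."""
    with open(path, "w") as fh:
        for i, j in g.edges:
            fields = [str(i), str(j)]
            if g.weighted:
                fields.append(repr(g.weight(i, j)))
            if g.timestamped:
                fields.append(repr(g.timestamp(i, j)))
            fh.write(delimiter.join(fields) + "\n")
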