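"""Molecular graphs, degree maps and degree-class edge partitions.

A molecule is modelled as a simple undirected graph: atoms are vertices,
bonds are edges.  Every irregularity index implemented in this package is an
edge sum of a function of the two endpoint degrees, so a graph enters the
computation only through its *degree-class edge partition*: the multiset of
canonical degree pairs ``(a, b)`` with ``a <= b``, one per edge, aggregated
into counts.

Besides plain vertex degrees the package supports *reverse degrees*
``c_v = Δ - d_v + 1`` (Δ the maximum degree of the graph), which swap the
roles of high- and low-degree vertices; a vertex of maximum degree has
reverse degree 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import networkx as nx

__all__ = [
    "MolecularGraph",
    "DegreeClassPartition",
    "GraphParseError",
    "GraphValidationError",
    "read_edge_list",
    "degrees",
    "reverse_degrees",
    "edge_degree_partition",
]


class GraphParseError(ValueError):
    """Malformed edge-list input (carries the offending line number)."""


class GraphValidationError(ValueError):
    """Input violates the simple-graph contract (self-loop, duplicate edge)."""


class MolecularGraph:
    """Simple undirected graph with opaque string vertex labels.

    Thin wrapper over :class:`networkx.Graph` that enforces simplicity on
    construction (no self-loops, no parallel edges).  Isolated vertices are
    permitted; they never contribute to any index, which iterate over edges.
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str]] = (),
        vertices: Iterable[str] = (),
    ) -> None:
        g = nx.Graph()
        g.add_nodes_from(vertices)
        for u, v in edges:
            if u == v:
                raise GraphValidationError(f"self-loop at vertex {u!r}")
            if g.has_edge(u, v):
                raise GraphValidationError(f"duplicate edge {u!r}-{v!r}")
            g.add_edge(u, v)
        self._g = g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "MolecularGraph":
        return cls(g.edges(), g.nodes())

    @property
    def vertices(self) -> set[str]:
        return set(self._g.nodes())

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self._g.edges()}

    def edge_list(self) -> list[tuple[str, str]]:
        return list(self._g.edges())

    @property
    def number_of_vertices(self) -> int:
        return self._g.number_of_nodes()

    @property
    def number_of_edges(self) -> int:
        return self._g.number_of_edges()

    def to_networkx(self) -> nx.Graph:
        return self._g.copy()

    def max_degree(self) -> int:
        if self.number_of_vertices == 0:
            raise GraphValidationError("maximum degree undefined on the empty graph")
        return max(d for _, d in self._g.degree())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"MolecularGraph(|V|={self.number_of_vertices}, "
            f"|E|={self.number_of_edges})"
        )


@dataclass
class DegreeClassPartition:
    """Counts of edges per canonical endpoint-degree pair ``(a, b)``, a <= b.

    This is a sufficient statistic for every index in the package: an index
    value is ``prefactor * sum(count * h(a, b))`` over the classes.
    """

    counts: dict[tuple[int, int], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        canon: dict[tuple[int, int], int] = {}
        for (a, b), n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count {n} for class ({a}, {b})")
            key = (a, b) if a <= b else (b, a)
            canon[key] = canon.get(key, 0) + n
        self.counts = canon

    def total(self) -> int:
        return sum(self.counts.values())

    def classes(self) -> list[tuple[int, int]]:
        return sorted(self.counts)

    def __getitem__(self, key: tuple[int, int]) -> int:
        a, b = key
        return self.counts.get((a, b) if a <= b else (b, a), 0)

    def __iter__(self):
        return iter(sorted(self.counts.items()))


def read_edge_list(stream: IO[str]) -> MolecularGraph:
    """Parse a plain-text edge list into a :class:`MolecularGraph`.

    Each non-empty, non-comment line holds two whitespace-separated vertex
    identifiers (arbitrary non-whitespace tokens).  ``#``-prefixed lines and
    blank lines are ignored.  Pair order is irrelevant (undirected graph);
    self-loops and duplicate edges are rejected.
    """
    edges: list[tuple[str, str]] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) != 2:
            raise GraphParseError(
                f"line {lineno}: expected two vertex identifiers, got {len(tokens)}"
            )
        u, v = tokens
        if u == v:
            raise GraphValidationError(f"line {lineno}: self-loop at vertex {u!r}")
        edges.append((u, v))
    try:
        return MolecularGraph(edges)
    except GraphValidationError as exc:
        raise GraphValidationError(f"edge list invalid: {exc}") from exc


def degrees(g: MolecularGraph) -> dict[str, int]:
    """Vertex degrees: number of edges incident to each vertex."""
    return dict(g.to_networkx().degree())


def reverse_degrees(g: MolecularGraph) -> dict[str, int]:
    """Reverse degrees ``c_v = Δ - d_v + 1`` with Δ the graph's max degree.

    Requires at least one edge so that Δ >= 1; on a regular graph all
    reverse degrees are 1.
    """
    if g.number_of_edges == 0:
        raise GraphValidationError(
            "reverse degrees undefined on an edgeless graph (Δ = 0)"
        )
    delta = g.max_degree()
    return {v: delta - d + 1 for v, d in degrees(g).items()}


def edge_degree_partition(
    g: MolecularGraph, dm: Mapping[str, int]
) -> DegreeClassPartition:
    """Group the edges of ``g`` by the (mapped) endpoint-value pair.

    ``dm`` is a degree map or reverse-degree map covering every endpoint.
    The resulting counts sum to ``|E|``.
    """
    counts: dict[tuple[int, int], int] = {}
    for u, v in g.edge_list():
        if u not in dm or v not in dm:
            missing = u if u not in dm else v
            raise KeyError(f"vertex {missing!r} missing from the degree map")
        a, b = sorted((dm[u], dm[v]))
        counts[(a, b)] = counts.get((a, b), 0) + 1
    return DegreeClassPartition(counts)
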