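r"""The twelve degree-based irregularity indices.

Each index is an edge sum ``prefactor * Σ_{uv ∈ E} h(d_u, d_v)`` of a
symmetric, nonnegative contribution ``h`` that vanishes on equal arguments —
so every index is zero exactly when no edge joins vertices of different
degree, in particular on every regular graph.  The registry:

========  =============================================  =========
name      h(x, y)                                        prefactor
========  =============================================  =========
IRDIF     \|x/y − y/x\|                                  1
AL        \|x − y\|  (Albertson, the edge imbalance)     1
IRL       \|ln x − ln y\|                                1
IRLU      \|x − y\| / min(x, y)                          1
IRLF      \|x − y\| / √(xy)                              1
IRF       (x − y)²                                       1
IRLA      2\|x − y\| / (x + y)                           1
IRD1      ln(1 + \|x − y\|)                              1
IRA       (x^−½ − y^−½)²                                 1
IRGA      ln((x + y) / (2√(xy)))                         1
IRB       (√x − √y)²                                     1
IRRt      \|x − y\|  (total irregularity)                1/2
========  =============================================  =========

IRLA's leading 2 is folded into ``h`` so all indices share one evaluation
path; IRRt keeps its 1/2 outside ``h`` to mirror the usual display.

Indices evaluated on reverse degrees (``c_v = Δ − d_v + 1``) are reported
under a ``C``-prefixed name (CAL, CIRF, ...).  Since the reverse map is an
affine reflection of the degrees, edge gaps are preserved
(``|c_u − c_v| = |d_u − d_v|``); hence CAL = AL, CIRF = IRF and
CIRRt = IRRt on every graph.

Rational contributions (IRDIF, AL, IRLU, IRF, IRLA, IRRt) are computed in
exact :class:`fractions.Fraction` arithmetic; the log/sqrt indices use
floating point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Union

from .graph import (
    DegreeClassPartition,
    MolecularGraph,
    degrees,
    edge_degree_partition,
    reverse_degrees,
)

__all__ = [
    "INDEX_NAMES",
    "IndexDefinition",
    "IndexValue",
    "get_index",
    "contribution",
    "compute_index",
    "compute_all",
    "compute_reverse_all",
    "reverse_name",
]

Number = Union[int, Fraction, float]


@dataclass(frozen=True)
class IndexDefinition:
    """A named irregularity index: per-edge contribution plus a prefactor."""

    name: str
    contribution: Callable[[int, int], Number]
    prefactor: Fraction = Fraction(1)
    #: True when h is rational for all positive-integer arguments, so the
    #: whole index evaluates exactly in Fraction arithmetic.
    rational: bool = False


def _irdif(x: int, y: int) -> Fraction:
    return abs(Fraction(x, y) - Fraction(y, x))


def _al(x: int, y: int) -> int:
    return abs(x - y)


def _irl(x: int, y: int) -> float:
    return abs(math.log(x) - math.log(y))


def _irlu(x: int, y: int) -> Fraction:
    return Fraction(abs(x - y), min(x, y))


def _irlf(x: int, y: int) -> float:
    return abs(x - y) / math.sqrt(x * y)


def _irf(x: int, y: int) -> int:
    return (x - y) ** 2


def _irla(x: int, y: int) -> Fraction:
    return Fraction(2 * abs(x - y), x + y)


def _ird1(x: int, y: int) -> float:
    return math.log(1 + abs(x - y))


def _ira(x: int, y: int) -> float:
    return (x ** -0.5 - y ** -0.5) ** 2


def _irga(x: int, y: int) -> float:
    return math.log((x + y) / (2.0 * math.sqrt(x * y)))


def _irb(x: int, y: int) -> float:
    return (math.sqrt(x) - math.sqrt(y)) ** 2


_REGISTRY: dict[str, IndexDefinition] = {
    d.name: d
    for d in [
        IndexDefinition("IRDIF", _irdif, rational=True),
        IndexDefinition("AL", _al, rational=True),
        IndexDefinition("IRL", _irl),
        IndexDefinition("IRLU", _irlu, rational=True),
        IndexDefinition("IRLF", _irlf),
        IndexDefinition("IRF", _irf, rational=True),
        IndexDefinition("IRLA", _irla, rational=True),
        IndexDefinition("IRD1", _ird1),
        IndexDefinition("IRA", _ira),
        IndexDefinition("IRGA", _irga),
        IndexDefinition("IRB", _irb),
        IndexDefinition("IRRt", _al, prefactor=Fraction(1, 2), rational=True),
    ]
}

#: Canonical ordering of the twelve indices.
INDEX_NAMES: tuple[str, ...] = tuple(_REGISTRY)


def reverse_name(name: str) -> str:
    """Reverse-flavor display name: C-prefixed (AL -> CAL, IRF -> CIRF)."""
    return "C" + name


def get_index(name: str) -> IndexDefinition:
    """Look up an index definition; accepts C-prefixed reverse names too."""
    key = name
    if key not in _REGISTRY and key.startswith("C") and key[1:] in _REGISTRY:
        key = key[1:]
    try:
        return _REGISTRY[key]
    except KeyError:
        raise KeyError(
            f"unknown irregularity index {name!r}; known: {', '.join(_REGISTRY)}"
        ) from None


def contribution(name: str, x: int, y: int) -> Number:
    """Per-edge contribution h(x, y) of the named index.

    Symmetric and zero on x == y; arguments must be positive integers.
    Note the IRRt prefactor 1/2 is *not* included here.
    """
    if x < 1 or y < 1:
        raise ValueError(f"degrees must be positive integers, got ({x}, {y})")
    return get_index(name).contribution(x, y)


@dataclass(frozen=True)
class IndexValue:
    """A computed index value with its flavor (degree or reverse)."""

    name: str
    flavor: str  # "degree" | "reverse"
    value: Number

    def __float__(self) -> float:
        return float(self.value)


def compute_index(
    p: DegreeClassPartition, name: str, flavor: str = "degree"
) -> IndexValue:
    """Evaluate one index over a degree-class partition.

    ``value = prefactor * Σ_classes count(a,b) * h(a,b)``; exact rational
    where h is rational, float otherwise.
    """
    defn = get_index(name)
    acc: Number = Fraction(0) if defn.rational else 0.0
    for (a, b), n in p:
        if n:
            acc += n * defn.contribution(a, b)
    value = defn.prefactor * acc if defn.rational else float(defn.prefactor) * acc
    display = reverse_name(defn.name) if flavor == "reverse" else defn.name
    return IndexValue(display, flavor, value)


def compute_all(p: DegreeClassPartition) -> list[IndexValue]:
    """All twelve degree-flavor index values over a partition."""
    return [compute_index(p, name) for name in INDEX_NAMES]


def compute_reverse_all(g: MolecularGraph) -> list[IndexValue]:
    """All twelve reverse-flavor index values of a graph.

    Equivalent to partitioning the edges by reverse-degree pairs and
    evaluating each index class-wise.  Requires at least one edge.
    """
    rp = edge_degree_partition(g, reverse_degrees(g))
    return [compute_index(rp, name, flavor="reverse") for name in INDEX_NAMES]


def compute_degree_all(g: MolecularGraph) -> list[IndexValue]:
    """All twelve degree-flavor index values of a graph."""
    return compute_all(edge_degree_partition(g, degrees(g)))
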