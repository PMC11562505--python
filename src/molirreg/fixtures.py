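"""Deterministic toy-graph generators and a brute-force index oracle.

The generators cover the standard small families (paths, cycles, stars,
complete bipartite graphs) plus seeded uniform random simple graphs.  The
oracle re-implements every index as a direct edge-by-edge sum with inline
formulas — an independent code path from the class-wise evaluation in
:mod:`molirreg.indices`, used to cross-check it.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass

from .graph import MolecularGraph

__all__ = ["FixtureSpec", "make_fixture", "brute_force_index"]

FAMILIES = ("path", "cycle", "star", "complete_bipartite", "random_simple")


@dataclass(frozen=True)
class FixtureSpec:
    """A toy-graph request: family name, size tuple, optional seed.

    sizes: path (n >= 2 vertices), cycle (n >= 3), star (k >= 1 leaves),
    complete_bipartite (m, n >= 1), random_simple (n vertices, m edges;
    seed required, reproducible).
    """

    family: str
    size: tuple[int, ...]
    seed: int | None = None


def _labels(n: int) -> list[str]:
    return [f"v{i}" for i in range(n)]


def make_fixture(spec: FixtureSpec) -> MolecularGraph:
    """Build the requested toy graph with canonical vertex labels v0, v1, ..."""
    fam, size = spec.family, spec.size
    if fam == "path":
        (n,) = size
        if n < 2:
            raise ValueError("path needs >= 2 vertices")
        v = _labels(n)
        return MolecularGraph(zip(v, v[1:]))
    if fam == "cycle":
        (n,) = size
        if n < 3:
            raise ValueError("cycle needs >= 3 vertices")
        v = _labels(n)
        return MolecularGraph(list(zip(v, v[1:])) + [(v[-1], v[0])])
    if fam == "star":
        (k,) = size
        if k < 1:
            raise ValueError("star needs >= 1 leaf")
        v = _labels(k + 1)
        return MolecularGraph((v[0], leaf) for leaf in v[1:])
    if fam == "complete_bipartite":
        m, n = size
        if m < 1 or n < 1:
            raise ValueError("complete bipartite needs both parts >= 1")
        left = [f"a{i}" for i in range(m)]
        right = [f"b{i}" for i in range(n)]
        return MolecularGraph((u, w) for u in left for w in right)
    if fam == "random_simple":
        n, m = size
        if n < 1 or m < 0:
            raise ValueError("random graph needs n >= 1, m >= 0")
        all_pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        if m > len(all_pairs):
            raise ValueError(f"m = {m} exceeds the {len(all_pairs)} possible edges")
        rng = random.Random(spec.seed)
        chosen = rng.sample(all_pairs, m)
        v = _labels(n)
        # isolated vertices are kept: they exercise the degree-0 path
        return MolecularGraph(((v[i], v[j]) for i, j in chosen), vertices=v)
    raise ValueError(f"unknown fixture family {spec.family!r}; known: {FAMILIES}")


# Inline contributions, deliberately duplicated from the definitions rather
# than imported, so the oracle is an independent code path.
_H = {
    "IRDIF": lambda x, y: abs(x / y - y / x),
    "AL": lambda x, y: abs(x - y),
    "IRL": lambda x, y: abs(math.log(x) - math.log(y)),
    "IRLU": lambda x, y: abs(x - y) / min(x, y),
    "IRLF": lambda x, y: abs(x - y) / math.sqrt(x * y),
    "IRF": lambda x, y: (x - y) ** 2,
    "IRLA": lambda x, y: 2 * abs(x - y) / (x + y),
    "IRD1": lambda x, y: math.log(1 + abs(x - y)),
    "IRA": lambda x, y: (1 / math.sqrt(x) - 1 / math.sqrt(y)) ** 2,
    "IRGA": lambda x, y: math.log((x + y) / (2 * math.sqrt(x * y))),
    "IRB": lambda x, y: (math.sqrt(x) - math.sqrt(y)) ** 2,
    "IRRt": lambda x, y: abs(x - y),
}


def brute_force_index(g: MolecularGraph, name: str, flavor: str = "degree") -> float:
    """Reference index value by direct summation over the edge list.

    Degrees are tallied from the edge list; the reverse flavor substitutes
    c = Δ - d + 1.  Requires >= 1 edge for the reverse flavor.
    """
    base = name[1:] if name.startswith("C") and name[1:] in _H else name
    if base not in _H:
        raise KeyError(f"unknown irregularity index {name!r}")
    edges = g.edge_list()
    deg: dict[str, int] = {v: 0 for v in g.vertices}
    for u, v in edges:
        deg[u] += 1
        deg[v] += 1
    if flavor == "reverse":
        if not edges:
            raise ValueError("reverse flavor needs at least one edge")
        delta = max(deg.values())
        deg = {v: delta - d + 1 for v, d in deg.items()}
    h = _H[base]
    total = sum(h(deg[u], deg[v]) for u, v in edges)
    return 0.5 * total if base == "IRRt" else float(total)
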