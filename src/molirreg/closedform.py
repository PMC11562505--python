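"""Closed-form derivation over parametric edge partitions.

For a graph family whose degree-class edge counts are bilinear polynomials
in two size parameters ``r`` and ``s`` (basis ``{rs, r, s, 1}``), every
edge-sum index has a closed form in the same basis:

    value(r, s) = c_rs * rs + c_r * r + c_s * s + c_0,

obtained by multiplying each class's per-edge contribution ``h(a, b)`` by
its count polynomial and summing coefficient-wise.  Two evaluation modes are
exposed:

``exact``
    ``h`` evaluated exactly (rational arithmetic where possible, floating
    point for log/sqrt contributions).
``paper_rounded``
    irrational contributions are rounded to 4 decimal places *before* being
    multiplied by the count polynomials — the convention conventionally used
    when such closed forms are tabulated at 4-decimal precision; rational
    contributions stay exact.  All coefficients in this mode are exact
    rationals (decimals over 10^4), so downstream table values carry no
    floating-point noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Sequence, Union

from .indices import get_index, reverse_name

__all__ = [
    "CoeffTuple",
    "ParametricPartition",
    "ClosedForm",
    "DerivationReport",
    "round4",
    "derive_closed_form",
    "compare_to_theorem",
]

Number = Union[int, Fraction, float]
CoeffTuple = tuple[Number, Number, Number, Number]

MODES = ("exact", "paper_rounded")
FLAVORS = ("degree", "reverse")


def round4(x: Number) -> Fraction:
    """Round to 4 decimal places (half away from zero), as an exact Fraction."""
    q = Decimal(repr(float(x))).quantize(Decimal("0.0001"), rounding=ROUND_HALF_UP)
    return Fraction(q)


@dataclass(frozen=True)
class ParametricPartition:
    """Degree classes with bilinear count polynomials over ``{rs, r, s, 1}``.

    ``classes`` maps each canonical degree pair ``(a, b)``, a <= b, to an
    integer coefficient 4-tuple ``(k_rs, k_r, k_s, k_0)`` meaning
    ``count(r, s) = k_rs*rs + k_r*r + k_s*s + k_0``.  Counts must evaluate
    to nonnegative integers for all integer r, s >= 1; this is checked at
    evaluation time.
    """

    classes: tuple[tuple[tuple[int, int], tuple[int, int, int, int]], ...]

    def __post_init__(self) -> None:
        for (a, b), coeffs in self.classes:
            if a > b:
                raise ValueError(f"class key ({a}, {b}) not canonical (need a <= b)")
            if a < 1:
                raise ValueError(f"degrees must be >= 1, got class ({a}, {b})")
            if len(coeffs) != 4:
                raise ValueError(
                    "count polynomials must live in the bilinear basis "
                    "{rs, r, s, 1}: expected a 4-tuple of coefficients, got "
                    f"{coeffs!r}"
                )

    def max_degree(self) -> int:
        return max(b for (_, b), _ in self.classes)

    def count(self, key: tuple[int, int], r: int, s: int) -> int:
        for (a, b), (krs, kr, ks, k0) in self.classes:
            if (a, b) == key:
                n = krs * r * s + kr * r + ks * s + k0
                if n < 0:
                    raise ValueError(
                        f"class ({a}, {b}) count {n} negative at (r, s) = ({r}, {s})"
                    )
                return n
        raise KeyError(key)

    def evaluate(self, r: int, s: int) -> dict[tuple[int, int], int]:
        if r < 1 or s < 1:
            raise ValueError(f"require r, s >= 1, got ({r}, {s})")
        return {key: self.count(key, r, s) for key, _ in self.classes}

    def total_coefficients(self) -> tuple[int, int, int, int]:
        """Coefficient-wise sum over classes: the |E| polynomial."""
        totals = [0, 0, 0, 0]
        for _, coeffs in self.classes:
            for i, c in enumerate(coeffs):
                totals[i] += c
        return tuple(totals)  # type: ignore[return-value]

    def __add__(self, other: "ParametricPartition") -> "ParametricPartition":
        return ParametricPartition(self.classes + other.classes)


@dataclass(frozen=True)
class ClosedForm:
    """``value(r, s) = c_rs*rs + c_r*r + c_s*s + c_0`` for one index."""

    name: str
    flavor: str
    coefficients: CoeffTuple
    mode: str = "exact"

    def evaluate(self, r: int, s: int) -> Number:
        if r < 1 or s < 1:
            raise ValueError(f"require r, s >= 1, got ({r}, {s})")
        c_rs, c_r, c_s, c_0 = self.coefficients
        return c_rs * r * s + c_r * r + c_s * s + c_0

    def as_floats(self) -> tuple[float, float, float, float]:
        return tuple(float(c) for c in self.coefficients)  # type: ignore[return-value]


def _reverse_classes(pp: ParametricPartition) -> ParametricPartition:
    """Map degree classes to reverse-degree classes via c = Δ − d + 1.

    Δ is taken as the largest degree appearing in any class.  The pair
    (a, b) maps to the canonical ordering of (Δ−b+1, Δ−a+1); counts are
    unchanged.
    """
    delta = pp.max_degree()
    mapped = []
    for (a, b), coeffs in pp.classes:
        x, y = sorted((delta - b + 1, delta - a + 1))
        mapped.append(((x, y), coeffs))
    return ParametricPartition(tuple(mapped))


def derive_closed_form(
    pp: ParametricPartition,
    name: str,
    flavor: str = "degree",
    mode: str = "exact",
) -> ClosedForm:
    """Derive the closed form of an index over a parametric partition.

    Coefficients are ``prefactor * Σ_classes h(a, b) * count-coefficients``,
    with ``h`` rounded per the mode (see module docstring).  For the reverse
    flavor the classes are first mapped through the reverse-degree
    reflection.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if flavor not in FLAVORS:
        raise ValueError(f"flavor must be one of {FLAVORS}, got {flavor!r}")
    defn = get_index(name)
    classes = _reverse_classes(pp) if flavor == "reverse" else pp
    exact_rational = defn.rational or mode == "paper_rounded"
    coeffs: list[Number] = (
        [Fraction(0)] * 4 if exact_rational else [0.0, 0.0, 0.0, 0.0]
    )
    for (a, b), ks in classes.classes:
        h = defn.contribution(a, b)
        if mode == "paper_rounded" and not defn.rational:
            h = round4(h)
        for i, k in enumerate(ks):
            coeffs[i] += h * k
    pref = defn.prefactor if exact_rational else float(defn.prefactor)
    coeffs = [pref * c for c in coeffs]
    display = reverse_name(defn.name) if flavor == "reverse" else defn.name
    return ClosedForm(display, flavor, tuple(coeffs), mode)


@dataclass(frozen=True)
class DerivationReport:
    """Derived closed forms for one index, checked against the published one."""

    name: str
    flavor: str
    derived_exact: ClosedForm
    derived_rounded: ClosedForm
    theorem: ClosedForm
    max_deviation_exact: float
    max_deviation_rounded: float


def _max_dev(a: ClosedForm, b: ClosedForm) -> float:
    return max(
        abs(x - y) for x, y in zip(a.as_floats(), b.as_floats())
    )


def compare_to_theorem(
    name: str, flavor: str = "degree"
) -> DerivationReport:
    """Re-derive one InP[r,s] closed form and compare with the published one.

    The published coefficient tuples for all 24 forms are bundled in
    :mod:`molirreg.reference`.
    """
    from .inp import inp_parametric_partition
    from .reference import theorem_closed_form

    pp = inp_parametric_partition()
    exact = derive_closed_form(pp, name, flavor, "exact")
    rounded = derive_closed_form(pp, name, flavor, "paper_rounded")
    thm = theorem_closed_form(name, flavor)
    return DerivationReport(
        name=thm.name,
        flavor=flavor,
        derived_exact=exact,
        derived_rounded=rounded,
        theorem=thm,
        max_deviation_exact=_max_dev(exact, thm),
        max_deviation_rounded=_max_dev(rounded, thm),
    )


def sweep_reports(flavors: Sequence[str] = FLAVORS) -> list[DerivationReport]:
    """Derivation reports for every index in every requested flavor."""
    from .indices import INDEX_NAMES

    return [compare_to_theorem(n, f) for f in flavors for n in INDEX_NAMES]
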