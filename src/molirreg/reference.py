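"""Published reference values for the InP[r,s] lattice family.

Coefficient tuples of the 24 published closed forms (12 degree-based, 12 on
reverse degrees) and the two published 12x5 numeric tables at
(r, s) in {(1,1), ..., (5,5)}, kept verbatim for cross-checking.

Coefficients printed as fractions (8/3, 112/15, 32/3, 77/3, 44/5, 24/5) are
stored as exact rationals; 4-decimal printed coefficients are stored as
exact decimals over 10^4.  Two table entries are known to contradict the
closed forms they tabulate — the whole degree-flavor IRLA row and the
degree-flavor AL value at (4,4) (printed 279; the closed form and the
reverse-flavor CAL row both give 276).  This module keeps the printed
values untouched; the discrepancy handling lives in :mod:`molirreg.report`.
"""

from __future__ import annotations

from fractions import Fraction

from .closedform import ClosedForm

__all__ = [
    "THEOREM_COEFFICIENTS",
    "PUBLISHED_TABLES",
    "TABLE_PAIRS",
    "KNOWN_DISCREPANT_CELLS",
    "theorem_closed_form",
]


def _d(s: str) -> Fraction:
    """Exact rational for a printed decimal literal."""
    return Fraction(s)


F = Fraction

#: (flavor, display name) -> (c_rs, c_r, c_s, c_0), exact rationals.
THEOREM_COEFFICIENTS: dict[tuple[str, str], tuple[Fraction, ...]] = {
    ("degree", "IRDIF"): (F(6), F(21), F(21), F(-15)),
    ("degree", "AL"): (F(8), F(20), F(20), F(-12)),
    ("degree", "IRL"): (_d("2.7724"), _d("8.3176"), _d("8.3176"), _d("-5.5452")),
    ("degree", "IRLU"): (F(4), F(16), F(16), F(-12)),
    ("degree", "IRLF"): (_d("2.8284"), _d("8.8284"), _d("8.8284"), F(-6)),
    ("degree", "IRF"): (F(16), F(52), F(52), F(-36)),
    ("degree", "IRLA"): (F(8, 3), F(112, 15), F(112, 15), F(-24, 5)),
    ("degree", "IRD1"): (_d("4.3944"), _d("9.9396"), _d("9.9396"), _d("-5.5452")),
    ("degree", "IRA"): (_d("0.1716"), _d("1.1716"), _d("1.1716"), F(-1)),
    ("degree", "IRGA"): (_d("0.2356"), _d("1.128"), _d("1.128"), _d("-0.8924")),
    ("degree", "IRB"): (_d("1.3724"), _d("5.3724"), _d("5.3724"), F(-4)),
    ("degree", "IRRt"): (F(4), F(10), F(10), F(-6)),
    ("reverse", "CIRDIF"): (F(32, 3), F(77, 3), F(77, 3), F(-15)),
    ("reverse", "CAL"): (F(8), F(20), F(20), F(-12)),
    ("reverse", "CIRL"): (_d("4.3944"), _d("9.9396"), _d("9.9396"), _d("-5.5452")),
    ("reverse", "CIRLU"): (F(8), F(20), F(20), F(-12)),
    ("reverse", "CIRLF"): (_d("4.6188"), _d("10.6188"), _d("10.6188"), F(-6)),
    ("reverse", "CIRF"): (F(16), F(52), F(52), F(-36)),
    ("reverse", "CIRLA"): (F(4), F(44, 5), F(44, 5), F(-24, 5)),
    ("reverse", "CIRD1"): (_d("4.3944"), _d("9.9396"), _d("9.9396"), _d("-5.5452")),
    ("reverse", "CIRA"): (_d("0.7144"), _d("1.7144"), _d("1.7144"), F(-1)),
    ("reverse", "CIRGA"): (_d("0.5752"), _d("1.4676"), _d("1.4676"), _d("-0.8924")),
    ("reverse", "CIRB"): (_d("2.1436"), _d("6.1436"), _d("6.1436"), F(-4)),
    ("reverse", "CIRRt"): (F(4), F(10), F(10), F(-6)),
}

#: Column order of the published tables.
TABLE_PAIRS: tuple[tuple[int, int], ...] = ((1, 1), (2, 2), (3, 3), (4, 4), (5, 5))

#: Published table cells, verbatim strings per (flavor, name) row.
PUBLISHED_TABLES: dict[tuple[str, str], tuple[str, ...]] = {
    ("degree", "IRDIF"): ("33", "93", "165", "249", "345"),
    ("degree", "AL"): ("36", "100", "180", "279", "388"),
    ("degree", "IRL"): ("13.8624", "38.8148", "69.312", "105.354", "146.9408"),
    ("degree", "IRLU"): ("24", "68", "120", "180", "248"),
    ("degree", "IRLF"): ("14.4852", "40.6272", "72.426", "109.8816", "152.994"),
    ("degree", "IRF"): ("84", "236", "420", "636", "884"),
    ("degree", "IRLA"): ("42.6667", "95.4667", "153.6", "217.0667", "285.8667"),
    ("degree", "IRD1"): ("18.7284", "51.7908", "93.642", "144.282", "203.7108"),
    ("degree", "IRA"): ("1.5148", "4.3728", "7.574", "11.1184", "15.006"),
    ("degree", "IRGA"): ("1.5992", "4.562", "7.996", "11.9012", "16.2776"),
    ("degree", "IRB"): ("8.1172", "22.9792", "40.586", "60.9376", "84.034"),
    ("degree", "IRRt"): ("18", "50", "90", "138", "194"),
    ("reverse", "CIRDIF"): ("47", "130.3333", "235", "361", "508.3333"),
    ("reverse", "CAL"): ("36", "100", "180", "276", "388"),
    ("reverse", "CIRL"): ("18.7284", "51.7908", "93.642", "144.282", "203.7108"),
    ("reverse", "CIRLU"): ("36", "100", "180", "276", "388"),
    ("reverse", "CIRLF"): ("19.8564", "54.9504", "99.282", "152.8512", "215.658"),
    ("reverse", "CIRF"): ("84", "236", "420", "636", "884"),
    ("reverse", "CIRLA"): ("16.8", "46.4", "84", "129.6", "183.2"),
    ("reverse", "CIRD1"): ("18.7284", "51.7908", "93.642", "144.282", "203.7108"),
    ("reverse", "CIRA"): ("3.1432", "8.7152", "15.716", "24.1456", "34.004"),
    ("reverse", "CIRGA"): ("2.618", "7.2788", "13.09", "20.0516", "28.1636"),
    ("reverse", "CIRB"): ("10.4308", "29.1488", "52.154", "79.4464", "111.026"),
    ("reverse", "CIRRt"): ("18", "50", "90", "138", "194"),
}

#: Cells whose printed values contradict the published closed forms:
#: the whole degree IRLA row plus degree AL at (4,4).
KNOWN_DISCREPANT_CELLS: frozenset[tuple[str, str, tuple[int, int]]] = frozenset(
    {("degree", "IRLA", pair) for pair in TABLE_PAIRS}
    | {("degree", "AL", (4, 4))}
)


def theorem_closed_form(name: str, flavor: str = "degree") -> ClosedForm:
    """The published closed form for one index, as a :class:`ClosedForm`."""
    from .indices import get_index, reverse_name

    defn = get_index(name)
    display = reverse_name(defn.name) if flavor == "reverse" else defn.name
    try:
        coeffs = THEOREM_COEFFICIENTS[(flavor, display)]
    except KeyError:
        raise KeyError(f"no published closed form for {display!r} ({flavor})") from None
    return ClosedForm(display, flavor, coeffs, mode="paper_rounded")
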