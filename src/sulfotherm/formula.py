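"""Chemical-formula parsing, serialization and molar masses.

Supports the formula dialect needed for culture-medium recipes and a
small geochemical species database: element symbols with integer
subscripts, one level of parenthesized groups ("(NH4)2SO4"), hydrate
suffixes ("MgSO4·7H2O", also written with '.' or '*'), and trailing
charge designators ("+", "-2", "^2-").  Counts are exact rationals so
that downstream balance checks are exact.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, Iterator, Mapping


class FormulaError(ValueError):
    """Raised when a chemical formula cannot be parsed."""


#: IUPAC 2021 standard atomic weights (conventional values), g/mol.
ATOMIC_WEIGHTS: Dict[str, float] = {
    "H": 1.008, "B": 10.81, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998403163, "Na": 22.98976928, "Mg": 24.305, "P": 30.973761998,
    "S": 32.06, "Cl": 35.45, "K": 39.0983, "Ca": 40.078, "Mn": 54.938043,
    "Fe": 55.845, "Co": 58.933194, "Ni": 58.6934, "Cu": 63.546,
    "Zn": 65.38, "Se": 78.971, "Mo": 95.95, "V": 50.9415, "W": 183.84,
    "Si": 28.085, "Al": 26.9815385, "Br": 79.904, "I": 126.90447,
}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")
_HYDRATE_SEP = ("·", ".", "*")


@dataclass(frozen=True)
class ElementCount:
    """Exact element counts plus net charge of one chemical entity.

    ``counts`` maps element symbols to positive rational counts
    (rationals support fractional hydrates and average formulas);
    ``charge`` is the signed integer net charge.
    """

    counts: Mapping[str, Fraction] = field(default_factory=dict)
    charge: int = 0

    def __post_init__(self) -> None:
        clean = {el: Fraction(n) for el, n in self.counts.items() if n != 0}
        for el, n in clean.items():
            if n < 0:
                raise FormulaError(f"negative count for element {el!r}")
            if el not in ATOMIC_WEIGHTS:
                raise FormulaError(f"unknown element symbol {el!r}")
        object.__setattr__(self, "counts", dict(sorted(clean.items())))

    def __getitem__(self, el: str) -> Fraction:
        return self.counts.get(el, Fraction(0))

    def __iter__(self) -> Iterator[str]:
        return iter(self.counts)

    def items(self):
        return self.counts.items()

    def __add__(self, other: "ElementCount") -> "ElementCount":
        tot = dict(self.counts)
        for el, n in other.items():
            tot[el] = tot.get(el, Fraction(0)) + n
        return ElementCount(tot, self.charge + other.charge)

    def scaled(self, k) -> "ElementCount":
        k = Fraction(k)
        return ElementCount({el: n * k for el, n in self.counts.items()},
                            int(self.charge * k))


def _parse_fragment(frag: str) -> Dict[str, Fraction]:
    """Parse a charge-free, hydrate-free fragment with <=1 paren level."""
    counts: Dict[str, Fraction] = {}

    def add(el: str, n: Fraction) -> None:
        if el not in ATOMIC_WEIGHTS:
            raise FormulaError(f"unknown element symbol {el!r} in {frag!r}")
        counts[el] = counts.get(el, Fraction(0)) + n

    pos = 0
    while pos < len(frag):
        ch = frag[pos]
        if ch == "(":
            end = frag.find(")", pos)
            if end < 0:
                raise FormulaError(f"unclosed '(' in {frag!r}")
            inner = _parse_fragment(frag[pos + 1:end])
            m = re.match(r"\d+", frag[end + 1:])
            mult = Fraction(m.group()) if m else Fraction(1)
            for el, n in inner.items():
                add(el, n * mult)
            pos = end + 1 + (m.end() if m else 0)
        else:
            m = _TOKEN.match(frag, pos)
            if not m or not m.group(1):
                raise FormulaError(f"malformed token at {frag[pos:]!r} in {frag!r}")
            add(m.group(1), Fraction(m.group(2) or 1))
            pos = m.end()
    return counts


def _split_charge(formula: str) -> tuple[str, int]:
    """Strip a trailing charge designator: '+', '-2', '^2-', '+2'."""
    m = re.search(r"\^(\d*)([+-])$", formula)  # caret form: "^2-", "^+"
    if m:
        mag = int(m.group(1) or 1)
        return formula[: m.start()], mag if m.group(2) == "+" else -mag
    m = re.search(r"([+-])(\d*)$", formula)    # suffix form: "-2", "+"
    if not m:
        return formula, 0
    mag = int(m.group(2) or 1)
    return formula[: m.start()], mag if m.group(1) == "+" else -mag


def parse_formula(formula: str) -> ElementCount:
    """Parse a chemical formula string into exact element counts.

    >>> parse_formula("MgSO4·7H2O")["H"]
    Fraction(14, 1)
    >>> parse_formula("SO4-2").charge
    -2
    """
    if not formula or not formula.strip():
        raise FormulaError("empty formula")
    body, charge = _split_charge(formula.strip())
    # species-name conventions: trailing phase tags like "(g)"/"(aq)" are
    # not part of the formula proper
    body = re.sub(r"\((g|aq|cr|l|s)\)$", "", body)
    counts: Dict[str, Fraction] = {}
    for i, part in enumerate(re.split("[" + re.escape("".join(_HYDRATE_SEP)) + "]", body)):
        part = part.strip()
        if not part:
            raise FormulaError(f"empty fragment in {formula!r}")
        m = re.match(r"(\d+)(?=[A-Z(])", part) if i > 0 else None
        mult = Fraction(m.group(1)) if m else Fraction(1)
        frag = part[m.end():] if m else part
        for el, n in _parse_fragment(frag).items():
            counts[el] = counts.get(el, Fraction(0)) + n * mult
    return ElementCount(counts, charge)


def serialize_formula(ec: ElementCount) -> str:
    """Canonical serialization (Hill-ish order: C, H, then alphabetical)."""
    order = sorted(ec.counts, key=lambda el: (el != "C", el != "H", el))

    def fmt(n: Fraction) -> str:
        return "" if n == 1 else (str(n.numerator) if n.denominator == 1 else str(n))

    body = "".join(f"{el}{fmt(ec[el])}" for el in order)
    z = ec.charge
    if z == 0:
        return body
    return body + ("+" if z > 0 else "-") + (str(abs(z)) if abs(z) > 1 else "")


def molar_mass(formula: ElementCount | str) -> float:
    """Molar mass in g/mol from standard atomic weights.

    Accepts either a parsed :class:`ElementCount` or a formula string.
    """
    ec = parse_formula(formula) if isinstance(formula, str) else formula
    return float(sum(ATOMIC_WEIGHTS[el] * float(n) for el, n in ec.items()))
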