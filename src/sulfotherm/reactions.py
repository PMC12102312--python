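"""Reaction definitions, parsing, balance validation and electron counting.

Stoichiometric coefficients are exact rationals (negative for
reactants, positive for products) so element/charge balance checks are
exact, never float-fuzzy.  Reactions are written one per line as e.g.::

    rxn1: 3 H2S + 1 SO4-2 + 2 H+ = 4 S0 + 4 H2O

Electron transfer counts are derived from formal oxidation states of
the redox-active elements (S, N here); for comproportionation and
disproportionation — where the *net* element oxidation-state change is
zero — atoms on each side are paired in oxidation-state order and the
total upward transfer is counted.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

from .database import SpeciesDatabase, data_path, default_database


class ReactionError(ValueError):
    """Raised for malformed or unbalanced reactions."""


#: Formal oxidation states of the redox-active element in each species.
#: Maps species name -> (element, oxidation state per atom).
OXIDATION_STATES: Dict[str, Tuple[str, int]] = {
    "H2S": ("S", -2), "HS-": ("S", -2), "H2S(g)": ("S", -2),
    "S0": ("S", 0),
    "SO4-2": ("S", 6), "HSO4-": ("S", 6),
    "NH4+": ("N", -3), "NH3": ("N", -3),
    "N2": ("N", 0), "N2(g)": ("N", 0),
    "NO2-": ("N", 3), "NO3-": ("N", 5),
}


@dataclass(frozen=True)
class ReactionDef:
    """A chemical reaction as a signed stoichiometry map.

    ``nu`` maps species names to rational coefficients, negative for
    reactants and positive for products; zero entries are dropped at
    construction.  ``electrons`` may be supplied explicitly; otherwise
    :func:`electrons_transferred` derives it from oxidation states.
    """

    label: str
    nu: Mapping[str, Fraction] = field(default_factory=dict)
    electrons: Optional[Fraction] = None

    def __post_init__(self) -> None:
        clean = {sp: Fraction(c) for sp, c in self.nu.items() if c != 0}
        object.__setattr__(self, "nu", clean)

    @property
    def reactants(self) -> Dict[str, Fraction]:
        return {sp: -c for sp, c in self.nu.items() if c < 0}

    @property
    def products(self) -> Dict[str, Fraction]:
        return {sp: c for sp, c in self.nu.items() if c > 0}

    def reversed(self) -> "ReactionDef":
        return ReactionDef(self.label + " (reversed)",
                           {sp: -c for sp, c in self.nu.items()},
                           self.electrons)

    def __add__(self, other: "ReactionDef") -> "ReactionDef":
        nu = dict(self.nu)
        for sp, c in other.nu.items():
            nu[sp] = nu.get(sp, Fraction(0)) + c
        return ReactionDef(f"{self.label} + {other.label}", nu)

    def scaled(self, k) -> "ReactionDef":
        k = Fraction(k)
        return ReactionDef(self.label, {sp: c * k for sp, c in self.nu.items()},
                           None if self.electrons is None else self.electrons * k)

    def __str__(self) -> str:
        def side(d: Dict[str, Fraction]) -> str:
            return " + ".join(f"{c} {sp}" for sp, c in sorted(d.items()))
        return f"{side(self.reactants)} = {side(self.products)}"


@dataclass(frozen=True)
class BalanceReport:
    """Per-element and charge residuals of a reaction (products minus
    reactants); all-zero iff the reaction is balanced."""

    element_residuals: Dict[str, Fraction]
    charge_residual: Fraction

    @property
    def balanced(self) -> bool:
        return self.charge_residual == 0 and all(
            r == 0 for r in self.element_residuals.values())

    def __str__(self) -> str:
        if self.balanced:
            return "balanced"
        bad = {el: str(r) for el, r in self.element_residuals.items() if r != 0}
        return f"unbalanced: elements {bad}, charge {self.charge_residual}"


_TERM = re.compile(r"^\s*(\d+(?:/\d+)?)?\s*(\S+)\s*$")


def parse_reaction(line: str, label: str = "") -> ReactionDef:
    """Parse a one-line reaction, ``"3 H2S + 1 SO4-2 + 2 H+ = 4 S0 + 4 H2O"``.

    A leading ``label:`` prefix is honoured.  Coefficients may be
    integers or fractions; a missing coefficient means 1.
    """
    text = line.strip()
    if ":" in text.split("=")[0] and not label:
        label, text = (s.strip() for s in text.split(":", 1))
    if text.count("=") != 1:
        raise ReactionError(f"reaction needs exactly one '=': {line!r}")
    lhs, rhs = text.split("=")
    nu: Dict[str, Fraction] = {}

    def take(side: str, sign: int) -> None:
        for term in side.split(" + "):
            m = _TERM.match(term)
            if not m:
                raise ReactionError(f"malformed term {term!r} in {line!r}")
            coeff, name = m.groups()
            c = Fraction(coeff) if coeff else Fraction(1)
            nu[name] = nu.get(name, Fraction(0)) + sign * c

    take(lhs, -1)
    take(rhs, +1)
    return ReactionDef(label or text, nu)


def parse_reaction_file(path: str | Path) -> List[ReactionDef]:
    """Read a plain-text reaction file (one reaction per line, '#' comments)."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(parse_reaction(line))
    return out


def validate_reaction(rxn: ReactionDef,
                      db: Optional[SpeciesDatabase] = None) -> BalanceReport:
    """Check element and charge balance against the species database.

    Raises :class:`ReactionError` for unknown species or an empty
    reaction; imbalance is *reported*, not raised.
    """
    db = db or default_database()
    if not rxn.reactants or not rxn.products:
        raise ReactionError(
            f"{rxn.label!r}: needs at least one reactant and one product")
    residuals: Dict[str, Fraction] = {}
    charge = Fraction(0)
    for sp, c in rxn.nu.items():
        if sp not in db:
            raise ReactionError(f"{rxn.label!r}: unknown species {sp!r}")
        f = db[sp].formula
        for el, n in f.items():
            residuals[el] = residuals.get(el, Fraction(0)) + n * c
        charge += f.charge * c
    residuals = {el: r for el, r in residuals.items()}
    return BalanceReport(residuals, charge)


def electrons_transferred(rxn: ReactionDef,
                          db: Optional[SpeciesDatabase] = None) -> Fraction:
    """Moles of electrons transferred per mole of reaction as written.

    For each redox-active element, reactant- and product-side atoms are
    expanded with their formal oxidation states, sorted, and paired in
    order; the summed positive oxidation-state increases across pairs
    count the electrons.  This sorted pairing minimises double counting
    and yields the field-standard values (6 e- for sulfur
    comproportionation: three S(-II) atoms rise to S(0)).
    """
    if rxn.electrons is not None:
        return rxn.electrons
    db = db or default_database()
    total = Fraction(0)
    elements = {OXIDATION_STATES[sp][0] for sp in rxn.nu if sp in OXIDATION_STATES}
    for el in sorted(elements):
        reac: List[Tuple[int, Fraction]] = []   # (ox state, atom count)
        prod: List[Tuple[int, Fraction]] = []
        for sp, c in rxn.nu.items():
            if sp not in OXIDATION_STATES or OXIDATION_STATES[sp][0] != el:
                continue
            n_atoms = db[sp].formula[el] * abs(c)
            (prod if c > 0 else reac).append((OXIDATION_STATES[sp][1], n_atoms))
        reac.sort()
        prod.sort()
        if sum(n for _, n in reac) != sum(n for _, n in prod):
            raise ReactionError(
                f"{rxn.label!r}: element {el} unbalanced; cannot count electrons")
        # pair atoms in oxidation-state order, summing upward transfers
        i = j = 0
        reac = [list(t) for t in reac]
        prod = [list(t) for t in prod]
        while i < len(reac) and j < len(prod):
            n = min(reac[i][1], prod[j][1])
            d = prod[j][0] - reac[i][0]
            if d > 0:
                total += n * d
            reac[i][1] -= n
            prod[j][1] -= n
            if reac[i][1] == 0:
                i += 1
            if prod[j][1] == 0:
                j += 1
    return total


from functools import lru_cache


@lru_cache(maxsize=1)
def load_reaction_library() -> Dict[str, ReactionDef]:
    """All packaged reactions keyed by label (Rxn 1, dissolution and
    acid-dissociation equilibria, and the ammonium-oxidation suite)."""
    lib: Dict[str, ReactionDef] = {}
    rxn_dir = data_path("reactions")
    for path in sorted(Path(rxn_dir).glob("*.txt")):
        for rxn in parse_reaction_file(path):
            if rxn.label in lib:
                raise ReactionError(f"duplicate reaction label {rxn.label!r}")
            lib[rxn.label] = rxn
    return lib


#: canonical sulfur comproportionation: 3 H2S + SO4-2 + 2 H+ = 4 S0 + 4 H2O
def comproportionation() -> ReactionDef:
    return load_reaction_library()["comproportionation"]
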