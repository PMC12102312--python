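"""Culture-medium recipes: grams-per-liter salts to component molalities.

A recipe is a list of (salt formula, g/L) plus an acid (mol/L) and
molar amendments.  Salts dissociate into database components via an
explicit packaged map (no speciation guessed at parse time), and
molarity is mapped to molality with the dilute-solution convention
1 L medium ≈ 1 kg water (<1 % error at these ionic strengths).
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Sequence, Tuple

from .database import data_path
from .formula import molar_mass, parse_formula
from .speciation import SolutionComposition


class RecipeError(ValueError):
    """Raised for salts without a dissociation rule."""


@lru_cache(maxsize=1)
def dissociation_map() -> Dict[str, List[Tuple[str, float]]]:
    out: Dict[str, List[Tuple[str, float]]] = {}
    with open(data_path("salt_dissociation.csv"), newline="") as fh:
        for row in csv.DictReader(fh):
            out.setdefault(row["salt"], []).append(
                (row["component"], float(row["count"])))
    return out


@dataclass(frozen=True)
class Recipe:
    """A medium recipe in the units a protocol prints."""

    name: str
    T: float                      # incubation temperature, K
    pH: float                     # adjusted pH
    salts_g_per_L: Sequence[Tuple[str, float]] = field(default_factory=tuple)
    acid: Tuple[str, float] | None = None          # (formula, mol/L)
    extras_mol_per_L: Sequence[Tuple[str, float]] = field(default_factory=tuple)
    gases: Dict[str, float] = field(default_factory=dict)  # bar


def recipe_to_composition(recipe: Recipe) -> SolutionComposition:
    """Total component molalities of a recipe (1 L ≈ 1 kg water).

    Salt formulas are parsed (hydrates included) for molar mass; the
    dissociation map routes each salt's moles into component totals.
    ``extras`` are already component-resolved molar amendments, e.g.
    ("S(-II)", 0.002) for 2 mM sulfide.
    """
    dmap = dissociation_map()
    totals: Dict[str, float] = {}

    def add_salt(formula: str, mol: float) -> None:
        # canonical '·' hydrate separator for map lookup
        key = formula.replace(".", "·").replace("*", "·")
        if key not in dmap:
            raise RecipeError(f"no dissociation rule for salt {formula!r}")
        for component, n in dmap[key]:
            totals[component] = totals.get(component, 0.0) + n * mol

    for formula, grams in recipe.salts_g_per_L:
        add_salt(formula, grams / molar_mass(parse_formula(formula)))
    if recipe.acid is not None:
        add_salt(recipe.acid[0], recipe.acid[1])
    for component, mol in recipe.extras_mol_per_L:
        totals[component] = totals.get(component, 0.0) + mol
    return SolutionComposition(T=recipe.T, pH=recipe.pH, totals=totals,
                               gases=recipe.gases)
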