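"""The packaged species-property database.

Each species carries 25 °C / 1 bar standard-state formation properties
plus the equation-of-state block its phase requires: revised-HKF
coefficients for aqueous species, Maier-Kelley heat-capacity
coefficients for gases, crystalline solids and liquid water.  Units are
J-based throughout (the conventional HKF scale factors and the cal->J
conversion are applied when the CSV resource is generated).
"""
from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Dict, Iterator, Optional

from .formula import ElementCount, parse_formula

PHASES = ("aqueous", "gas", "crystalline", "liquid-water")


class DatabaseError(ValueError):
    """Raised for malformed or inconsistent database entries."""


@dataclass(frozen=True)
class HKFBlock:
    """Revised-HKF coefficients, descaled J units.

    a1 (J/mol/bar), a2 (J/mol), a3 (J K/mol/bar), a4 (J K/mol) form the
    pressure block, which is inert at the package's fixed 1 bar; c1
    (J/mol/K) and c2 (J K/mol) the temperature block; omega (J/mol) the
    Born coefficient, held at its 25 °C value.
    """

    a1: float = 0.0
    a2: float = 0.0
    a3: float = 0.0
    a4: float = 0.0
    c1: float = 0.0
    c2: float = 0.0
    omega: float = 0.0


@dataclass(frozen=True)
class MaierKelleyBlock:
    """Cp = a + b*T + c/T**2, J/mol/K with T in K."""

    a: float = 0.0
    b: float = 0.0
    c: float = 0.0


@dataclass(frozen=True)
class SpeciesRecord:
    """One chemical species with standard-state properties.

    ``G_f``/``H_f`` are formation Gibbs energy / enthalpy (J/mol) and
    ``S`` the third-law entropy (J/mol/K), all at 25 °C and 1 bar.
    ``a_ring`` is the B-dot ion-size parameter in angstroms (aqueous
    ions only).
    """

    name: str
    formula: ElementCount
    charge: int
    phase: str
    G_f: float
    H_f: float
    S: float
    hkf: Optional[HKFBlock] = None
    mk: Optional[MaierKelleyBlock] = None
    a_ring: float = 0.0
    source: str = ""

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise DatabaseError(f"{self.name}: unknown phase {self.phase!r}")
        if self.charge != self.formula.charge:
            raise DatabaseError(
                f"{self.name}: charge {self.charge} inconsistent with "
                f"formula charge {self.formula.charge}")
        if not (math.isfinite(self.G_f) and math.isfinite(self.S)):
            raise DatabaseError(f"{self.name}: non-finite G_f or S")
        if self.phase == "aqueous" and self.hkf is None:
            raise DatabaseError(f"{self.name}: aqueous species needs an HKF block")
        if self.phase != "aqueous" and self.mk is None:
            raise DatabaseError(f"{self.name}: non-aqueous species needs a "
                                "Maier-Kelley block")


class SpeciesDatabase:
    """Name-keyed collection of :class:`SpeciesRecord`."""

    def __init__(self, records: Dict[str, SpeciesRecord]):
        self._records = dict(records)

    def __getitem__(self, name: str) -> SpeciesRecord:
        try:
            return self._records[name]
        except KeyError:
            raise KeyError(f"species {name!r} not in database") from None

    def __contains__(self, name: str) -> bool:
        return name in self._records

    def __iter__(self) -> Iterator[SpeciesRecord]:
        return iter(self._records.values())

    def __len__(self) -> int:
        return len(self._records)

    def names(self):
        return list(self._records)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpeciesDatabase":
        records: Dict[str, SpeciesRecord] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(r for r in fh if not r.startswith("#")):
                rec = _record_from_row(row)
                if rec.name in records:
                    raise DatabaseError(f"duplicate species {rec.name!r}")
                records[rec.name] = rec
        return cls(records)


def _f(row: dict, key: str, default: float = 0.0) -> float:
    v = (row.get(key) or "").strip()
    return float(v) if v else default


def _record_from_row(row: dict) -> SpeciesRecord:
    phase = row["phase"].strip()
    name = row["name"].strip()
    formula = parse_formula(row["formula"].strip())
    charge = int(row["z"])
    # the formula column omits charge; graft the declared charge on
    formula = ElementCount(formula.counts, charge)
    hkf = mk = None
    if phase == "aqueous":
        hkf = HKFBlock(a1=_f(row, "a1"), a2=_f(row, "a2"), a3=_f(row, "a3"),
                       a4=_f(row, "a4"), c1=_f(row, "c1"), c2=_f(row, "c2"),
                       omega=_f(row, "omega"))
    else:
        mk = MaierKelleyBlock(a=_f(row, "mk_a"), b=_f(row, "mk_b"),
                              c=_f(row, "mk_c"))
    return SpeciesRecord(
        name=name, formula=formula, charge=charge, phase=phase,
        G_f=float(row["G_f_J"]), H_f=_f(row, "H_f_J"), S=float(row["S_J_K"]),
        hkf=hkf, mk=mk, a_ring=_f(row, "a_ring"), source=row.get("source", ""))


def data_path(name: str) -> Path:
    """Path of a packaged data resource."""
    return Path(str(resources.files("sulfotherm") / "data" / name))


@lru_cache(maxsize=None)
def default_database() -> SpeciesDatabase:
    """The packaged species database (cached)."""
    return SpeciesDatabase.from_csv(data_path("species.csv"))
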