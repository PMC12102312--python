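"""Reaction quotients, in-situ Gibbs energies, normalizations, energy
landscapes and the ammonium-oxidation exclusion screen.

The central identity is dGr = dG0r + RT ln Q, evaluated per mole of
reaction as written; because the sign convention (negative =
exergonic) coexists in the field with "energy yield" phrasing, a
positive-yield field (-dGr) is always carried, together with exact
rational rescalings per mole of electrons and per mole of S0 produced.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from itertools import product as iterproduct
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .constants import rt_ln10
from .database import SpeciesDatabase, default_database
from .hkf import delta_G0_reaction
from .reactions import (ReactionDef, electrons_transferred,
                        load_reaction_library, validate_reaction)
from .scenarios import Scenario
from .speciation import (SpeciatedSolution, dissolved_species_of,
                         gas_to_activity, speciate)


class ActivityError(KeyError):
    """A reaction species has no resolvable activity."""


@dataclass(frozen=True)
class EnergyResult:
    """Energetics of one reaction under one scenario.

    ``dG0r``/``dGr`` are J per mole of reaction as written; ``yield_``
    is -dGr (positive when exergonic); ``per_electron`` and ``per_S0``
    are exact rescalings by the electron count and the S0 coefficient
    (None when S0 is not produced).  ``converged`` propagates the
    speciation convergence flag.
    """

    label: str
    T: float
    dG0r: float
    log10K: float
    log10Q: float
    dGr: float
    electrons: Optional[Fraction]
    per_electron: Optional[float]
    per_S0: Optional[float]
    converged: bool = True

    @property
    def yield_(self) -> float:
        return -self.dGr

    @property
    def exergonic(self) -> bool:
        return self.dGr < 0


def reaction_quotient(rxn: ReactionDef,
                      activities: Mapping[str, float]) -> float:
    """log10 Q = sum(nu_i log10 a_i) over the reaction's species.

    ``activities`` maps species name -> log10 activity; every species
    must be present (S0/H2O conventionally at 0).
    """
    try:
        return float(sum(float(c) * activities[sp]
                         for sp, c in rxn.nu.items()))
    except KeyError as exc:
        raise ActivityError(
            f"species {exc.args[0]!r} has no activity for {rxn.label!r}") from None


def resolve_activities(rxn: ReactionDef, scenario: Scenario,
                       sol: Optional[SpeciatedSolution] = None,
                       db: Optional[SpeciesDatabase] = None,
                       trace_log_activity: Optional[float] = None,
                       ) -> Dict[str, float]:
    """log10 activities for every species of ``rxn`` under ``scenario``.

    Resolution order per species: explicit scenario override; fixed
    conventions (crystalline solids and liquid water at unit activity,
    H+ at -pH, gas species at their partial pressure); the speciated
    solution; Henry-law coupling for dissolved gases whose component is
    not in the totals; finally ``trace_log_activity`` if given, else an
    error naming the species.
    """
    db = db or default_database()
    out: Dict[str, float] = {}
    need_speciation = []
    for sp in rxn.nu:
        if sp in scenario.overrides:
            out[sp] = float(scenario.overrides[sp])
        elif db[sp].phase in ("crystalline", "liquid-water"):
            out[sp] = 0.0
        elif sp == "H+":
            out[sp] = -scenario.pH
        elif db[sp].phase == "gas":
            p = scenario.gases.get(sp)
            if p is None or p <= 0:
                raise ActivityError(
                    f"gas {sp!r} has no partial pressure in {scenario.name!r}")
            out[sp] = math.log10(p)
        else:
            need_speciation.append(sp)
    if need_speciation:
        if sol is None:
            sol = speciate(scenario.composition, db)
        for sp in need_speciation:
            if sp in sol.species and sol.species[sp].molality > 0:
                out[sp] = sol.log_activity(sp)
                continue
            gas = _gas_source(sp, scenario)
            if gas is not None:
                a = gas_to_activity(gas, scenario.gases[gas], scenario.T, db)
                out[sp] = math.log10(a)
            elif trace_log_activity is not None:
                out[sp] = trace_log_activity
            else:
                raise ActivityError(
                    f"species {sp!r} has no activity under {scenario.name!r}")
    return out


def _gas_source(species: str, scenario: Scenario) -> Optional[str]:
    for gas, p in scenario.gases.items():
        if p > 0:
            try:
                if dissolved_species_of(gas) == species:
                    return gas
            except Exception:
                continue
    return None


def delta_G_r(rxn: ReactionDef, scenario: Scenario,
              db: Optional[SpeciesDatabase] = None,
              sol: Optional[SpeciatedSolution] = None,
              trace_log_activity: Optional[float] = None) -> EnergyResult:
    """Full energetics of ``rxn`` under ``scenario`` (dGr = dG0r + RT ln Q).

    Speciation is performed internally (or an existing
    :class:`SpeciatedSolution` may be passed to amortize it across
    reactions); its convergence flag propagates to the result.
    """
    db = db or default_database()
    report = validate_reaction(rxn, db)
    if not report.balanced:
        raise ValueError(f"{rxn.label!r} is {report}")
    converged = True
    needs_sol = any(
        sp not in scenario.overrides and db[sp].phase == "aqueous"
        and sp != "H+" for sp in rxn.nu)
    if needs_sol and sol is None:
        sol = speciate(scenario.composition, db)
    if sol is not None and needs_sol:
        converged = sol.converged
    T = scenario.T
    dG0, logK = delta_G0_reaction(rxn, T, db)
    acts = resolve_activities(rxn, scenario, sol, db, trace_log_activity)
    logQ = reaction_quotient(rxn, acts)
    dGr = dG0 + rt_ln10(T) * logQ
    ne = electrons_transferred(rxn, db)
    nS0 = rxn.nu.get("S0", Fraction(0))
    return EnergyResult(
        label=rxn.label, T=T, dG0r=dG0, log10K=logK, log10Q=logQ, dGr=dGr,
        electrons=ne if ne > 0 else None,
        per_electron=dGr / float(ne) if ne > 0 else None,
        per_S0=dGr / float(nS0) if nS0 > 0 else None,
        converged=converged)


def ammonium_oxidation_suite(scenario: Scenario,
                             extra: Sequence[ReactionDef] = (),
                             trace_log_activity: float = -6.0,
                             db: Optional[SpeciesDatabase] = None,
                             ) -> List[EnergyResult]:
    """Energetics of the six sulfate-reduction/ammonium-oxidation
    reactions under ``scenario``, sorted by dGr (most exergonic first).

    Product species absent from the medium (NO2-, NO3-) are assigned a
    trace activity of 1e-6 molal (detection-limit convention,
    adjustable); dissolved N2 follows the headspace via Henry's law.
    Any reaction failing balance validation aborts the suite.
    """
    db = db or default_database()
    lib = load_reaction_library()
    suite = [lib[k] for k in sorted(lib) if k.startswith("amox_")]
    suite += list(extra)
    for rxn in suite:
        rep = validate_reaction(rxn, db)
        if not rep.balanced:
            raise ValueError(f"suite aborted: {rxn.label!r} is {rep}")
    sol = speciate(scenario.composition, db)
    results = [delta_G_r(rxn, scenario, db, sol,
                         trace_log_activity=trace_log_activity)
               for rxn in suite]
    return sorted(results, key=lambda r: r.dGr)


@dataclass(frozen=True)
class LandscapeAxis:
    """One grid axis: ``variable`` is "T", "pH", or "log_a:<species>"."""

    variable: str
    values: Sequence[float]

    def __post_init__(self) -> None:
        if len(self.values) == 0:
            raise ValueError(f"empty axis {self.variable!r}")


@dataclass(frozen=True)
class LandscapeGrid:
    """Dense energy evaluation over environmental axes (long format)."""

    axes: Tuple[LandscapeAxis, ...]
    points: List[Tuple[Tuple[float, ...], EnergyResult]]

    def to_rows(self) -> List[dict]:
        rows = []
        for coords, res in self.points:
            row = {ax.variable: c for ax, c in zip(self.axes, coords)}
            row.update(dG0r_J=res.dG0r, log10K=res.log10K, log10Q=res.log10Q,
                       dGr_J=res.dGr, yield_J=res.yield_)
            rows.append(row)
        return rows


def _apply_axis(scenario: Scenario, variable: str, value: float) -> Scenario:
    if variable == "T":
        return scenario.with_T(value)
    if variable == "pH":
        return scenario.with_pH(value)
    if variable.startswith("log_a:"):
        return scenario.with_override(variable.split(":", 1)[1], value)
    raise ValueError(f"unknown landscape variable {variable!r}")


def landscape(rxn: ReactionDef, scenario: Scenario,
              axes: Sequence[LandscapeAxis],
              db: Optional[SpeciesDatabase] = None,
              trace_log_activity: Optional[float] = None) -> LandscapeGrid:
    """Evaluate ``rxn`` over the cartesian grid spanned by ``axes``.

    Each cell equals :func:`delta_G_r` at the corresponding point, so a
    1x1 grid reproduces the scalar evaluation exactly.
    """
    if not axes:
        raise ValueError("need at least one axis")
    points = []
    for coords in iterproduct(*(ax.values for ax in axes)):
        sc = scenario
        for ax, v in zip(axes, coords):
            sc = _apply_axis(sc, ax.variable, v)
        points.append((tuple(float(c) for c in coords),
                       delta_G_r(rxn, sc, db,
                                 trace_log_activity=trace_log_activity)))
    return LandscapeGrid(tuple(axes), points)
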