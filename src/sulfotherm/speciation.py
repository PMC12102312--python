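"""Fixed-pH aqueous speciation with B-dot activity coefficients.

The solver distributes each component's total molality among its
aqueous species by mass action at the measured pH (charge balance is
*not* imposed — pH is a measurement), with activity coefficients from
the B-dot extended Debye-Hückel model and ionic strength made
self-consistent by damped fixed-point iteration.  Neutral species get
gamma = 1; the proton activity is 10^-pH exactly; S0 and liquid water
have unit activity by convention.

The component -> species map is a CSV resource; each secondary species
is tied to its reference species by a packaged ionization reaction
whose log K(T) comes from the HKF engine.
"""
from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, Mapping, Optional

from .database import SpeciesDatabase, data_path, default_database
from .hkf import delta_G0_reaction
from .reactions import ReactionDef, load_reaction_library
from .water import WaterState, water_properties

MAX_ITER = 100
I_RTOL = 1e-10

#: components tracked in totals but excluded from speciation and ionic
#: strength (documented omission: mmol-level, redox-inert here)
INERT_COMPONENTS = ("phosphate",)


class SpeciationError(ValueError):
    """Raised for unknown components or unusable component maps."""


@dataclass(frozen=True)
class SolutionComposition:
    """Bulk composition: temperature, measured pH, component totals.

    ``totals`` holds molalities (mol/kg water) keyed by component name
    (e.g. ``"S(VI)"``, ``"S(-II)"``, ``"Na"``); ``gases`` optional
    partial pressures in bar keyed by gas species name.
    """

    T: float
    pH: float
    totals: Mapping[str, float] = field(default_factory=dict)
    gases: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "totals",
                           {k: float(v) for k, v in self.totals.items() if v != 0.0})
        object.__setattr__(self, "gases", dict(self.gases))
        for k, v in self.totals.items():
            if v < 0:
                raise ValueError(f"negative total for component {k!r}")
        if not (0.0 <= self.pH <= 14.0):
            raise ValueError(f"pH {self.pH} outside [0, 14]")

    def replace_total(self, component: str, value: float) -> "SolutionComposition":
        totals = dict(self.totals)
        totals[component] = value
        return SolutionComposition(self.T, self.pH, totals, self.gases)


@dataclass(frozen=True)
class SpeciesState:
    molality: float
    gamma: float
    log_activity: float


@dataclass(frozen=True)
class SpeciatedSolution:
    """Resolved per-species molalities, activity coefficients and
    activities (a = gamma * m / m°, m° = 1 mol/kg), plus the converged
    ionic strength."""

    T: float
    pH: float
    species: Dict[str, SpeciesState]
    ionic_strength: float
    iterations: int
    converged: bool

    def molality(self, name: str) -> float:
        return self.species[name].molality

    def gamma(self, name: str) -> float:
        return self.species[name].gamma

    def log_activity(self, name: str) -> float:
        return self.species[name].log_activity

    def activity(self, name: str) -> float:
        return 10.0 ** self.species[name].log_activity


def bdot_log_gamma(z: int, a_ring: float, I: float, water: WaterState) -> float:
    """log10 activity coefficient, B-dot extended Debye-Hückel.

    log10 gamma = -A z^2 sqrt(I) / (1 + å B sqrt(I)) + Bdot I for ions;
    exactly 0 for neutral species (the CO2-type salting-out term is
    omitted at the sub-0.5 molal ionic strengths this package targets).
    """
    if I < 0:
        raise ValueError("negative ionic strength")
    if z == 0 or I == 0.0:
        return 0.0
    sqI = math.sqrt(I)
    return -water.A * z * z * sqI / (1.0 + a_ring * water.B * sqI) \
        + water.bdot * I


@lru_cache(maxsize=1)
def component_map() -> Dict[str, dict]:
    """component -> {"reference": name, "secondary": [(name, rxn label)]}"""
    out: Dict[str, dict] = {}
    with open(data_path("components.csv"), newline="") as fh:
        for row in csv.DictReader(fh):
            comp = out.setdefault(row["component"],
                                  {"reference": None, "secondary": []})
            if row["role"] == "reference":
                comp["reference"] = row["species"]
            else:
                comp["secondary"].append((row["species"], row["reaction"]))
    return out


def _ionization_alpha(rxn: ReactionDef, sec: str, ref: str, pH: float,
                      logK: float) -> float:
    """Exponent alpha with log a(sec) = alpha + log a(ref).

    Requires nu(sec) and nu(ref) of magnitude 1 and opposite sign; the
    remaining participants must be H+ (activity 10^-pH) or H2O
    (activity 1).
    """
    nu = rxn.nu
    if abs(nu.get(sec, 0)) != 1 or abs(nu.get(ref, 0)) != 1:
        raise SpeciationError(
            f"ionization reaction {rxn.label!r} must be first-order in "
            f"{sec!r} and {ref!r}")
    rest = 0.0
    for sp, c in nu.items():
        if sp in (sec, ref, "H2O"):
            continue
        if sp == "H+":
            rest += float(c) * (-pH)
        else:
            raise SpeciationError(
                f"unsupported participant {sp!r} in {rxn.label!r}")
    sign = 1.0 if nu[sec] > 0 else -1.0
    return sign * (logK - rest)


def speciate(comp: SolutionComposition,
             db: Optional[SpeciesDatabase] = None) -> SpeciatedSolution:
    """Speciate a solution at fixed pH; deterministic fixed-point on I.

    Mass balance per component is conserved exactly by construction;
    convergence is declared when successive ionic strengths agree to
    1e-10 relative within 100 iterations, with 0.5 damping if the
    iteration oscillates.  Non-convergence is flagged, never silent.
    """
    db = db or default_database()
    lib = load_reaction_library()
    cmap = component_map()
    pH, T = comp.pH, comp.T
    water = water_properties(T)

    active = {}
    for name, total in comp.totals.items():
        if name in INERT_COMPONENTS:
            continue
        if name not in cmap:
            raise SpeciationError(f"unknown component {name!r}")
        active[name] = total

    # temperature-dependent log K of every ionization reaction involved
    logKs = {}
    for name in active:
        for sec, rlabel in cmap[name]["secondary"]:
            logKs[rlabel] = delta_G0_reaction(lib[rlabel], T, db)[1]
    logK_w = delta_G0_reaction(lib["water_ionization"], T, db)[1]

    a_H = 10.0 ** (-pH)

    def gamma_of(name: str, I: float) -> float:
        sp = db[name]
        return 10.0 ** bdot_log_gamma(sp.charge, sp.a_ring, I, water)

    I = 0.0
    iterations = 0
    converged = False
    damping_on = False
    prev_delta = None
    species: Dict[str, SpeciesState] = {}
    for iterations in range(1, MAX_ITER + 1):
        species = {}
        # background proton/hydroxide implied by the measured pH
        g_h = gamma_of("H+", I)
        m_h = a_H / g_h
        species["H+"] = SpeciesState(m_h, g_h, -pH)
        log_a_oh = logK_w + pH
        g_oh = gamma_of("OH-", I)
        species["OH-"] = SpeciesState(10.0 ** log_a_oh / g_oh, g_oh, log_a_oh)

        for name, total in active.items():
            ref = cmap[name]["reference"]
            g_ref = gamma_of(ref, I)
            ratios = []  # m(sec)/m(ref)
            for sec, rlabel in cmap[name]["secondary"]:
                alpha = _ionization_alpha(lib[rlabel], sec, ref, pH,
                                          logKs[rlabel])
                g_sec = gamma_of(sec, I)
                ratios.append((sec, g_sec, 10.0 ** alpha * g_ref / g_sec))
            m_ref = total / (1.0 + sum(r for _, _, r in ratios))
            species[ref] = SpeciesState(
                m_ref, g_ref,
                math.log10(m_ref * g_ref) if m_ref > 0 else -math.inf)
            for sec, g_sec, r in ratios:
                m_sec = m_ref * r
                species[sec] = SpeciesState(
                    m_sec, g_sec,
                    math.log10(m_sec * g_sec) if m_sec > 0 else -math.inf)

        I_new = 0.5 * sum(st.molality * db[name].charge ** 2
                          for name, st in species.items())
        delta = I_new - I
        if abs(delta) <= I_RTOL * max(I_new, 1e-30):
            I = I_new
            converged = True
            break
        if prev_delta is not None and delta * prev_delta < 0:
            damping_on = True  # oscillation detected
        I = I + 0.5 * delta if damping_on else I_new
        prev_delta = delta

    return SpeciatedSolution(T=T, pH=pH, species=species, ionic_strength=I,
                             iterations=iterations, converged=converged)


def gas_to_activity(gas: str, p_partial: float, T: float,
                    db: Optional[SpeciesDatabase] = None) -> float:
    """Activity of the dissolved species in Henry-law equilibrium with a
    gas at partial pressure ``p_partial`` (bar; fugacity coefficient 1).

    The dissolution reaction (e.g. ``H2S(g) = H2S``) must exist in the
    reaction library.  ppmv converts upstream as
    p = ppmv * 1e-6 * 1.013 bar.
    """
    if p_partial < 0:
        raise ValueError("negative partial pressure")
    if p_partial == 0.0:
        return 0.0
    rxn = dissolution_reaction(gas)
    logK = delta_G0_reaction(rxn, T, db or default_database())[1]
    return 10.0 ** (logK + math.log10(p_partial))


@lru_cache(maxsize=None)
def dissolution_reaction(gas: str) -> ReactionDef:
    """The packaged dissolution reaction consuming 1 mol of ``gas``."""
    for rxn in load_reaction_library().values():
        if rxn.nu.get(gas) == -1 and len(rxn.nu) == 2:
            return rxn
    raise SpeciationError(f"no dissolution reaction for gas {gas!r}")


def dissolved_species_of(gas: str) -> str:
    """Aqueous counterpart of a gas species per the dissolution reaction."""
    rxn = dissolution_reaction(gas)
    return next(sp for sp, c in rxn.nu.items() if c > 0)
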