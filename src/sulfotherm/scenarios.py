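"""Named environments: the Frasassi snottite in-situ scenario, the
comproportionation cultivation medium, TOML scenario files, and a
seeded random-scenario generator for property testing.

A scenario couples a bulk composition (T, pH, totals, gas partial
pressures) with optional free-activity overrides used for landscape
work; overrides win over speciation for the named species only.
"""
from __future__ import annotations

import tomllib
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Mapping, Optional

import numpy as np
from scipy.optimize import brentq

from .constants import CONST
from .database import data_path, default_database
from .recipe import Recipe, recipe_to_composition
from .speciation import SolutionComposition, speciate

T_INSITU = 286.55     # K: 13.4 C cave air / biofilm temperature
T_MEDIUM = 288.15     # K: 15 C incubation temperature


class ScenarioError(ValueError):
    """Raised when a scenario cannot be constructed (e.g. closure fails)."""


@dataclass(frozen=True)
class Scenario:
    """A named environment for reaction-energy evaluation.

    ``overrides`` maps species names to fixed log10 activities, taking
    precedence over speciation for those species only.
    """

    name: str
    composition: SolutionComposition
    overrides: Mapping[str, float] = field(default_factory=dict)
    seed: Optional[int] = None

    @property
    def T(self) -> float:
        return self.composition.T

    @property
    def pH(self) -> float:
        return self.composition.pH

    @property
    def gases(self) -> Mapping[str, float]:
        return self.composition.gases

    def with_override(self, species: str, log_a: float) -> "Scenario":
        ov = dict(self.overrides)
        ov[species] = log_a
        return replace(self, overrides=ov)

    def with_total(self, component: str, value: float) -> "Scenario":
        return replace(self,
                       composition=self.composition.replace_total(component, value))

    def with_pH(self, pH: float) -> "Scenario":
        c = self.composition
        return replace(self, composition=SolutionComposition(
            c.T, pH, c.totals, c.gases))

    def with_T(self, T: float) -> "Scenario":
        c = self.composition
        return replace(self, composition=SolutionComposition(
            T, c.pH, c.totals, c.gases))


def _charge_imbalance(comp: SolutionComposition) -> float:
    """Signed charge excess (mol charge/kg) of the speciated solution,
    proton included; zero when the pH-implied proton pool exactly
    balances the anions."""
    sol = speciate(comp)
    db = default_database()
    return sum(st.molality * db[name].charge
               for name, st in sol.species.items())


def frasassi_insitu(pH: float = 0.5, h2s_ppmv: float = 24.0,
                    T: float = T_INSITU) -> Scenario:
    """The snottite field-site scenario.

    Total sulfate is solved so that the free proton pool implied by the
    measured pH is exactly charge-balanced by the sulfuric-acid anions
    (operationalizing "sulfate inferred from pH"); dissolved H2S
    activity then follows from Henry-law equilibrium with the cave-air
    partial pressure during energy evaluation.  Arguments outside the
    field ranges (pH 0-1, 15-33 ppmv) warn but proceed.
    """
    if not (0.0 <= pH <= 1.0):
        warnings.warn(f"pH {pH} outside the field range 0-1", stacklevel=2)
    if not (15.0 <= h2s_ppmv <= 33.0):
        warnings.warn(f"{h2s_ppmv} ppmv outside the field range 15-33",
                      stacklevel=2)
    p_h2s = h2s_ppmv * 1e-6 * CONST.P_atm

    def f(s_tot: float) -> float:
        return _charge_imbalance(
            SolutionComposition(T, pH, {"S(VI)": s_tot},
                                {"H2S(g)": p_h2s}))

    try:
        s_tot = brentq(f, 1e-10, 20.0, xtol=1e-14, rtol=1e-14)
    except ValueError as exc:
        raise ScenarioError(f"sulfate closure failed at pH {pH}: {exc}") from exc
    comp = SolutionComposition(T, pH, {"S(VI)": float(s_tot)},
                               {"H2S(g)": p_h2s})
    return Scenario(name=f"Frasassi in situ (pH {pH}, {h2s_ppmv} ppmv)",
                    composition=comp)


def comproportionation_medium() -> Scenario:
    """The cultivation-medium scenario, fully determined by the recipe."""
    raw = tomllib.loads(
        (data_path("recipes") / "comproportionation_medium.toml").read_text())
    recipe = Recipe(
        name=raw["name"],
        T=raw["T_C"] + 273.15,
        pH=raw["pH"],
        salts_g_per_L=[tuple(x) for x in raw["salts_g_per_L"]],
        acid=tuple(raw["acid"]),
        extras_mol_per_L=[tuple(x) for x in raw["extras_mol_per_L"]],
        gases=dict(raw.get("gases", {})),
    )
    return Scenario(name=recipe.name,
                    composition=recipe_to_composition(recipe))


#: components drawn by the random generator, log-uniform 1e-6..1e-1 mol/kg
_RANDOM_COMPONENTS = ("S(VI)", "S(-II)", "N(-III)", "Na", "Cl")

DEFAULT_RANGES = {
    "T_C": (0.0, 50.0),
    "pH": (0.0, 7.0),
    "log_total": (-6.0, -1.0),
    "h2s_ppmv": (0.0, 100.0),
}


def random_scenario(seed: int, ranges: Optional[dict] = None) -> Scenario:
    """A seeded random scenario emulating the field-data structure.

    Same seed, same scenario (single named PRNG stream); the seed is
    recorded on the result.  Totals are log-uniform, temperature and pH
    uniform within ``ranges`` (see :data:`DEFAULT_RANGES`).
    """
    r = dict(DEFAULT_RANGES, **(ranges or {}))
    for k, (lo, hi) in r.items():
        if not hi > lo:
            raise ValueError(f"degenerate range for {k!r}: {(lo, hi)}")
    rng = np.random.default_rng(seed)
    T = 273.15 + rng.uniform(*r["T_C"])
    pH = rng.uniform(*r["pH"])
    totals = {c: 10.0 ** rng.uniform(*r["log_total"])
              for c in _RANDOM_COMPONENTS}
    ppmv = rng.uniform(*r["h2s_ppmv"])
    gases = {"H2S(g)": ppmv * 1e-6 * CONST.P_atm} if ppmv > 0 else {}
    comp = SolutionComposition(float(T), float(pH),
                               {k: float(v) for k, v in totals.items()}, gases)
    return Scenario(name=f"random[{seed}]", composition=comp, seed=seed)


def load_scenario(path: str | Path) -> Scenario:
    """Read a scenario TOML (keys: name, T_C, pH, [gases],
    [totals_mmol_kg], [overrides])."""
    raw = tomllib.loads(Path(path).read_text())
    comp = SolutionComposition(
        T=raw["T_C"] + 273.15, pH=raw["pH"],
        totals={k: v * 1e-3 for k, v in raw.get("totals_mmol_kg", {}).items()},
        gases=dict(raw.get("gases", {})))
    return Scenario(name=raw.get("name", Path(path).stem), composition=comp,
                    overrides=dict(raw.get("overrides", {})))


def dump_scenario(sc: Scenario) -> str:
    """Serialize a scenario to TOML text (inverse of :func:`load_scenario`)."""
    lines = [f'name = "{sc.name}"',
             f"T_C = {sc.T - 273.15!r}",
             f"pH = {sc.pH!r}"]
    if sc.composition.totals:
        lines.append("\n[totals_mmol_kg]")
        lines += [f'"{k}" = {v * 1e3!r}'
                  for k, v in sc.composition.totals.items()]
    if sc.gases:
        lines.append("\n[gases]")
        lines += [f'"{k}" = {v!r}' for k, v in sc.gases.items()]
    if sc.overrides:
        lines.append("\n[overrides]")
        lines += [f'"{k}" = {v!r}' for k, v in sc.overrides.items()]
    return "\n".join(lines) + "\n"


def builtin_scenarios() -> Dict[str, Scenario]:
    """The shipped named scenarios."""
    return {
        "frasassi_insitu": frasassi_insitu(),
        "comproportionation_medium": comproportionation_medium(),
    }
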