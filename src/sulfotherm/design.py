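"""Inverse medium design: solve one free medium parameter so a target
reaction's Gibbs energy matches a target value (e.g. a field site's
catabolic energy), operationalizing energy-matched cultivation design.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

from scipy.optimize import brentq

from .database import SpeciesDatabase, default_database
from .energetics import EnergyResult, delta_G_r
from .reactions import ReactionDef
from .scenarios import Scenario

FREE_PARAMETERS = ("S(-II)", "S(VI)", "pH", "T")
BASES = ("reaction", "electron", "S0")
TOL_J = 1.0            # |dGr - target| convergence requirement, J/mol
MAX_ITER = 200


class DesignError(ValueError):
    """Raised when the target is not bracketed or the solve fails."""


@dataclass(frozen=True)
class DesignSpec:
    """One-parameter inverse design problem.

    ``target`` is a Gibbs energy in J per mole of the chosen ``basis``
    ("reaction" as written, "electron", or "S0" produced); ``free``
    names the adjustable quantity (a component total in mol/kg, pH, or
    T in K) and ``bounds`` its search interval.
    """

    reaction: ReactionDef
    target: float
    basis: str
    free: str
    bounds: Tuple[float, float]
    base: Scenario

    def __post_init__(self) -> None:
        if self.basis not in BASES:
            raise ValueError(f"basis must be one of {BASES}, got {self.basis!r}")
        if self.free not in FREE_PARAMETERS:
            raise ValueError(
                f"free parameter must be one of {FREE_PARAMETERS}, got {self.free!r}")
        lo, hi = self.bounds
        if not hi > lo:
            raise ValueError(f"degenerate bounds {self.bounds}")


@dataclass(frozen=True)
class DesignResult:
    value: float               # solved free-parameter value
    scenario: Scenario         # base scenario with the value substituted
    energy: EnergyResult       # achieved energetics
    achieved: float            # dGr on the requested basis, J/mol
    converged: bool


def _apply(scenario: Scenario, free: str, x: float) -> Scenario:
    if free == "pH":
        return scenario.with_pH(x)
    if free == "T":
        return scenario.with_T(x)
    return scenario.with_total(free, x)


def _on_basis(res: EnergyResult, basis: str) -> float:
    if basis == "reaction":
        return res.dGr
    if basis == "electron":
        if res.per_electron is None:
            raise DesignError(f"{res.label!r} transfers no electrons")
        return res.per_electron
    if res.per_S0 is None:
        raise DesignError(f"{res.label!r} produces no S0")
    return res.per_S0


def solve_design(spec: DesignSpec,
                 db: Optional[SpeciesDatabase] = None) -> DesignResult:
    """Bracketed 1-D root-find of the free parameter.

    Requires the target to be bracketed by the bounds (checked up
    front; non-bracketing raises rather than clamping) and refines
    until the achieved energy is within 1 J/mol of the target.
    """
    db = db or default_database()

    def f(x: float) -> float:
        sc = _apply(spec.base, spec.free, x)
        return _on_basis(delta_G_r(spec.reaction, sc, db), spec.basis) \
            - spec.target

    lo, hi = spec.bounds
    f_lo, f_hi = f(lo), f(hi)
    if f_lo == 0.0:
        x = lo
    elif f_hi == 0.0:
        x = hi
    elif f_lo * f_hi > 0:
        raise DesignError(
            f"target {spec.target:.6g} J/mol not bracketed on "
            f"[{lo:.6g}, {hi:.6g}] (endpoint residuals {f_lo:.6g}, {f_hi:.6g})")
    else:
        x = float(brentq(f, lo, hi, xtol=1e-15, rtol=8.9e-16,
                         maxiter=MAX_ITER))
    scenario = _apply(spec.base, spec.free, x)
    energy = delta_G_r(spec.reaction, scenario, db)
    achieved = _on_basis(energy, spec.basis)
    return DesignResult(value=x, scenario=scenario, energy=energy,
                        achieved=achieved,
                        converged=abs(achieved - spec.target) < TOL_J)
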