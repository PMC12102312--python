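"""Temperature-dependent standard-state Gibbs energies at 1 bar.

Aqueous species use the revised Helgeson-Kirkham-Flowers equations of
state restricted to P = Pr = 1 bar, where the a1-a4 pressure block
drops out identically and the Born coefficient omega is held at its
25 °C value (a < 0.1 kJ/mol approximation below 100 °C).  Gases,
crystalline solids and liquid water use Maier-Kelley heat capacities
(Cp = a + bT + c/T^2) with closed-form integrals.  At Tr = 298.15 K
every path returns exactly the database formation energy.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

from .constants import CONST, rt_ln10
from .database import SpeciesDatabase, SpeciesRecord, default_database
from .reactions import ReactionDef, ReactionError, validate_reaction
from .water import dielectric_constant, water_properties


class CoefficientError(ValueError):
    """Raised when a species lacks the EoS block its phase requires."""


@dataclass(frozen=True)
class StandardStateResult:
    """Apparent standard partial molal Gibbs energy of one species."""

    name: str
    T: float
    G: float  # J/mol at (T, 1 bar)


def gibbs_aqueous_hkf(sp: SpeciesRecord, T: float) -> StandardStateResult:
    """Revised-HKF apparent standard Gibbs energy of an aqueous species.

    G(T) = Gf - S(T-Tr) - c1[T ln(T/Tr) - T + Tr]
           - c2[((1/(T-th) - 1/(Tr-th))((th-T)/th))
                - (T/th^2) ln(Tr(T-th)/(T(Tr-th)))]
           + omega (1/eps(T) - 1/eps(Tr)) + omega Y(Tr) (T-Tr)

    with th = 228 K; all (P - Pr) terms are identically zero at 1 bar.
    """
    if sp.phase != "aqueous" or sp.hkf is None:
        raise CoefficientError(f"{sp.name}: not an aqueous species with HKF block")
    Tr, th = CONST.Tr, CONST.theta
    k = sp.hkf
    if T == Tr:
        return StandardStateResult(sp.name, T, sp.G_f)
    c1_term = k.c1 * (T * math.log(T / Tr) - T + Tr)
    c2_term = k.c2 * (((1.0 / (T - th) - 1.0 / (Tr - th)) * ((th - T) / th))
                      - (T / th ** 2) * math.log(Tr * (T - th) / (T * (Tr - th))))
    w_ref = water_properties(Tr)
    born = k.omega * (1.0 / dielectric_constant(T) - 1.0 / w_ref.epsilon) \
        + k.omega * w_ref.Y * (T - Tr)
    G = sp.G_f - sp.S * (T - Tr) - c1_term - c2_term + born
    return StandardStateResult(sp.name, T, G)


def gibbs_nonaqueous(sp: SpeciesRecord, T: float) -> StandardStateResult:
    """Maier-Kelley standard Gibbs energy for gas / crystalline / water.

    G(T) = Gf - S(T-Tr) + int_Tr^T Cp dT - T int_Tr^T (Cp/T) dT with
    Cp = a + bT + c/T^2 in closed form.
    """
    if sp.phase == "aqueous" or sp.mk is None:
        raise CoefficientError(f"{sp.name}: no Maier-Kelley block")
    Tr = CONST.Tr
    a, b, c = sp.mk.a, sp.mk.b, sp.mk.c
    int_cp = a * (T - Tr) + 0.5 * b * (T * T - Tr * Tr) - c * (1.0 / T - 1.0 / Tr)
    int_cp_t = a * math.log(T / Tr) + b * (T - Tr) \
        - 0.5 * c * (1.0 / T ** 2 - 1.0 / Tr ** 2)
    G = sp.G_f - sp.S * (T - Tr) + int_cp - T * int_cp_t
    return StandardStateResult(sp.name, T, G)


def gibbs_energy(sp: SpeciesRecord, T: float) -> StandardStateResult:
    """Phase-dispatching standard-state Gibbs energy at (T, 1 bar)."""
    if sp.phase == "aqueous":
        return gibbs_aqueous_hkf(sp, T)
    return gibbs_nonaqueous(sp, T)


def delta_G0_reaction(rxn: ReactionDef, T: float,
                      db: Optional[SpeciesDatabase] = None,
                      check_balance: bool = True) -> Tuple[float, float]:
    """Standard-state reaction Gibbs energy and log10 K at (T, 1 bar).

    Returns ``(dG0_r, log10K)`` with dG0_r = sum(nu_i G_i(T)) in J/mol
    and log10 K = -dG0_r / (RT ln 10).  Refuses unbalanced reactions
    unless ``check_balance`` is disabled.
    """
    db = db or default_database()
    if check_balance and rxn.nu:
        report = validate_reaction(rxn, db)
        if not report.balanced:
            raise ReactionError(f"{rxn.label!r} is {report}")
    dG0 = sum(float(c) * gibbs_energy(db[sp], T).G for sp, c in rxn.nu.items())
    logK = -dG0 / rt_ln10(T)
    return dG0, logK


def log_k(rxn: ReactionDef, T: float,
          db: Optional[SpeciesDatabase] = None) -> float:
    """log10 of the equilibrium constant of ``rxn`` at (T, 1 bar)."""
    return delta_G0_reaction(rxn, T, db)[1]
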