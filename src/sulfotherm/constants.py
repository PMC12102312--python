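"""Physical constants shared across the package.

All energies are joules per mole internally; source tables given in
thermochemical calories are converted with the exact factor 4.184.
"""
from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ThermoConstants:
    """Immutable constants of the thermodynamic framework.

    ``theta`` and ``psi`` are the solvent constants of the revised HKF
    equations of state (228 K and 2600 bar).  ``psi`` is unused at the
    fixed 1 bar pressure of this package but kept for completeness.
    """

    R: float = 8.314462618          # J / mol / K
    Tr: float = 298.15              # K, reference temperature
    Pr: float = 1.0                 # bar, reference pressure
    theta: float = 228.0            # K, HKF solvent constant
    psi: float = 2600.0             # bar, HKF solvent constant
    cal: float = 4.184              # J per thermochemical calorie (exact)
    P_atm: float = 1.013            # bar, ambient total pressure for ppmv gas


CONST = ThermoConstants()

#: natural-log-to-log10 conversion of RT, J/mol per log10 unit
def rt_ln10(T: float) -> float:
    """R*T*ln(10) in J/mol, the energy per decade of reaction quotient."""
    import math

    return CONST.R * T * math.log(10.0)
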