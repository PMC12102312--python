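"""Solvent-water properties at 1 bar: dielectric constant, density,
Born Y function, and Debye-Hückel / B-dot parameters.

The dielectric constant uses the Bradley-Pitzer (1979) correlation (the
EQ3/6-lineage choice), density the Kell (1975) 1-atm polynomial, and
the B-dot parameter a linearly interpolated table.  Validity is the
1 bar liquid range, 0-100 °C; outside it a :class:`RangeError` is
raised — no silent extrapolation.
"""
from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np

from .database import data_path

T_MIN, T_MAX = 273.15, 373.15


class RangeError(ValueError):
    """Temperature outside the 0-100 °C, 1 bar validity range."""


@dataclass(frozen=True)
class WaterState:
    """Solvent properties at one temperature (1 bar).

    ``A``/``B`` are the Debye-Hückel slope parameters on the log10,
    molal scale (kg^1/2 mol^-1/2 and kg^1/2 mol^-1/2 Å^-1); ``bdot`` the
    extended-term coefficient (kg/mol); ``Y = (1/eps^2) d(eps)/dT`` the
    Born temperature function (1/K).
    """

    T: float
    epsilon: float
    rho: float
    Y: float
    A: float
    B: float
    bdot: float


@lru_cache(maxsize=1)
def _coefficients(path: str | None = None) -> dict:
    p = Path(path) if path else data_path("water_correlations.csv")
    with open(p, newline="") as fh:
        return {row["parameter"]: float(row["value"])
                for row in csv.DictReader(fh)}


@lru_cache(maxsize=1)
def _bdot_table(path: str | None = None):
    p = Path(path) if path else data_path("bdot.csv")
    with open(p, newline="") as fh:
        rows = [(float(r["T_C"]), float(r["bdot"])) for r in csv.DictReader(fh)]
    rows.sort()
    return np.array([r[0] for r in rows]), np.array([r[1] for r in rows])


def _check_range(T: float) -> None:
    if not (T_MIN <= T <= T_MAX):
        raise RangeError(
            f"T = {T} K outside liquid-water validity range "
            f"[{T_MIN}, {T_MAX}] K at 1 bar")


def dielectric_constant(T: float, P: float = 1.0) -> float:
    """Static dielectric constant of water (Bradley-Pitzer 1979)."""
    _check_range(T)
    c = _coefficients()
    D1000 = c["bp_U1"] * math.exp(c["bp_U2"] * T + c["bp_U3"] * T * T)
    C = c["bp_U4"] + c["bp_U5"] / (c["bp_U6"] + T)
    B = c["bp_U7"] + c["bp_U8"] / T + c["bp_U9"] * T
    return D1000 + C * math.log((B + P) / (B + 1000.0))


def _depsilon_dT(T: float, P: float = 1.0) -> float:
    """Analytic temperature derivative of the Bradley-Pitzer correlation."""
    c = _coefficients()
    D1000 = c["bp_U1"] * math.exp(c["bp_U2"] * T + c["bp_U3"] * T * T)
    dD1000 = D1000 * (c["bp_U2"] + 2.0 * c["bp_U3"] * T)
    C = c["bp_U4"] + c["bp_U5"] / (c["bp_U6"] + T)
    dC = -c["bp_U5"] / (c["bp_U6"] + T) ** 2
    B = c["bp_U7"] + c["bp_U8"] / T + c["bp_U9"] * T
    dB = -c["bp_U8"] / (T * T) + c["bp_U9"]
    ln_term = math.log((B + P) / (B + 1000.0))
    return dD1000 + dC * ln_term + C * dB * (1.0 / (B + P) - 1.0 / (B + 1000.0))


def density(T: float) -> float:
    """Liquid-water density at 1 atm in g/cm^3 (Kell 1975)."""
    _check_range(T)
    c = _coefficients()
    t = T - 273.15
    num = (c["kell_n0"] + c["kell_n1"] * t + c["kell_n2"] * t ** 2
           + c["kell_n3"] * t ** 3 + c["kell_n4"] * t ** 4
           + c["kell_n5"] * t ** 5)
    return num / (1.0 + c["kell_d1"] * t) / 1000.0


def water_properties(T: float) -> WaterState:
    """All solvent quantities at temperature ``T`` (K), 1 bar.

    The Debye-Hückel slopes follow their standard definitions from
    epsilon and rho:  A = 1.824829e6 rho^1/2 (eps T)^-3/2  and
    B = 50.29159 rho^1/2 (eps T)^-1/2 (per Å).
    """
    _check_range(T)
    eps = dielectric_constant(T)
    rho = density(T)
    Y = _depsilon_dT(T) / (eps * eps)
    A = 1.8248292e6 * math.sqrt(rho) / (eps * T) ** 1.5
    B = 50.291586 * math.sqrt(rho) / math.sqrt(eps * T)
    tc, bd = _bdot_table()
    bdot = float(np.interp(T - 273.15, tc, bd))
    return WaterState(T=T, epsilon=eps, rho=rho, Y=Y, A=A, B=B, bdot=bdot)
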