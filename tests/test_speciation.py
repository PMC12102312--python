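"""B-dot activity model and fixed-pH speciation solver."""
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sulfotherm.constants import CONST
from sulfotherm.hkf import delta_G0_reaction
from sulfotherm.speciation import (SolutionComposition, SpeciationError,
                                   bdot_log_gamma, gas_to_activity, speciate)
from sulfotherm.water import water_properties


class TestBdot:
    def test_infinite_dilution_limit(self):
        w = water_properties(298.15)
        assert bdot_log_gamma(-2, 4.0, 0.0, w) == 0.0

    def test_neutral_species_ideal(self):
        w = water_properties(298.15)
        assert bdot_log_gamma(0, 0.0, 0.5, w) == 0.0

    def test_hand_substitution(self):
        # log gamma = -A z^2 sqrt(I)/(1 + a B sqrt(I)) + Bdot I
        w = water_properties(298.15)
        I, z, a = 0.1, -2, 4.0
        expected = (-w.A * 4 * math.sqrt(I)
                    / (1 + a * w.B * math.sqrt(I)) + w.bdot * I)
        assert bdot_log_gamma(z, a, I, w) == pytest.approx(expected, rel=1e-15)

    def test_negative_ionic_strength_rejected(self):
        with pytest.raises(ValueError):
            bdot_log_gamma(1, 4.0, -0.1, water_properties(298.15))


class TestSpeciate:
    def test_empty_solution_near_neutral(self):
        sol = speciate(SolutionComposition(298.15, 7.0, {}))
        # only the pH-implied background; ionic strength ~1e-7
        assert sol.converged
        assert sol.ionic_strength < 2e-7
        assert set(sol.species) == {"H+", "OH-"}

    def test_proton_activity_is_exactly_ph(self):
        sol = speciate(SolutionComposition(288.15, 1.0, {"S(VI)": 0.07}))
        assert sol.log_activity("H+") == -1.0

    def test_fifty_fifty_split_at_pk(self, db, library):
        # at pH = pK1 and infinite dilution, H2S and HS- are equimolal
        pK1 = -delta_G0_reaction(library["h2s_ionization"], 298.15, db)[1]
        sol = speciate(SolutionComposition(298.15, pK1, {"S(-II)": 1e-6}))
        ratio = sol.molality("H2S") / sol.molality("HS-")
        assert ratio == pytest.approx(1.0, rel=1e-3)

    def test_mass_balance_and_determinism(self, medium, medium_solution):
        sol = medium_solution
        comp = medium.composition
        pairs = {"S(VI)": ("SO4-2", "HSO4-"), "S(-II)": ("H2S", "HS-"),
                 "N(-III)": ("NH4+", "NH3"), "C(IV)": ("CO2", "HCO3-")}
        for component, names in pairs.items():
            total = sum(sol.molality(n) for n in names)
            assert total == pytest.approx(comp.totals[component], rel=1e-12)
        again = speciate(comp)
        assert again.ionic_strength == sol.ionic_strength  # bit-identical
        assert all(again.species[n] == sol.species[n] for n in sol.species)

    def test_medium_dominated_by_bisulfate(self, medium_solution):
        # pH 1 sits below the second ionization constant of sulfuric acid
        frac = medium_solution.molality("HSO4-") / (
            medium_solution.molality("HSO4-")
            + medium_solution.molality("SO4-2"))
        assert frac > 0.5

    def test_medium_ionic_strength_in_bdot_domain(self, medium_solution):
        assert 0.0 < medium_solution.ionic_strength < 0.5

    def test_gamma_approaches_unity_at_dilution(self, medium):
        gammas = []
        for scale in (1.0, 1e-3, 1e-6):
            comp = SolutionComposition(
                medium.T, 7.0,
                {k: v * scale for k, v in medium.composition.totals.items()})
            gammas.append(speciate(comp).gamma("SO4-2"))
        assert gammas[0] < gammas[1] < gammas[2]
        # the pH 7 proton/hydroxide background floors I near 1e-7, so
        # gamma approaches but cannot exactly reach 1
        assert gammas[-1] == pytest.approx(1.0, abs=5e-3)

    def test_unknown_component_rejected(self):
        with pytest.raises(SpeciationError):
            speciate(SolutionComposition(298.15, 7.0, {"kryptonite": 1e-3}))

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=60)
    def test_mass_balance_on_random_scenarios(self, seed):
        from sulfotherm.scenarios import random_scenario
        sc = random_scenario(seed)
        sol = speciate(sc.composition)
        assert sol.converged
        pairs = {"S(VI)": ("SO4-2", "HSO4-"), "S(-II)": ("H2S", "HS-"),
                 "N(-III)": ("NH4+", "NH3")}
        for component, names in pairs.items():
            total = sum(sol.molality(n) for n in names)
            assert total == pytest.approx(
                sc.composition.totals[component], rel=1e-12)


class TestGasCoupling:
    def test_zero_pressure_limit(self):
        assert gas_to_activity("H2S(g)", 0.0, 286.55) == 0.0

    def test_henry_linearity(self):
        a1 = gas_to_activity("H2S(g)", 1e-5, 286.55)
        a2 = gas_to_activity("H2S(g)", 2e-5, 286.55)
        assert a2 == pytest.approx(2 * a1, rel=1e-12)

    def test_mid_range_cave_air(self, db, library):
        # 24 ppmv at 13.4 C: a = K(286.55 K) * 2.43e-5 (chained by hand)
        T = 286.55
        logK = delta_G0_reaction(library["h2s_dissolution"], T, db)[1]
        p = 24e-6 * CONST.P_atm
        assert gas_to_activity("H2S(g)", p, T) == pytest.approx(
            10.0 ** logK * p, rel=1e-12)

    def test_missing_dissolution_reaction(self):
        with pytest.raises(SpeciationError):
            gas_to_activity("Xe(g)", 1e-3, 298.15)
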