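"""Shipped scenarios, recipe conversion, and the random generator."""
import numpy as np
import pytest

from sulfotherm.database import default_database
from sulfotherm.recipe import Recipe, RecipeError, recipe_to_composition
from sulfotherm.scenarios import (dump_scenario, frasassi_insitu,
                                  load_scenario, random_scenario)
from sulfotherm.speciation import speciate


class TestRecipe:
    def test_single_salt(self):
        comp = recipe_to_composition(Recipe(
            "x", 288.15, 1.0, salts_g_per_L=[("Na2SO4", 2.42)]))
        # 2.42 g / 142.04 g/mol, 1 L ~ 1 kg water
        assert comp.totals["Na"] == pytest.approx(0.03408, rel=2e-3)
        assert comp.totals["S(VI)"] == pytest.approx(0.01704, rel=2e-3)

    def test_empty_recipe(self):
        comp = recipe_to_composition(Recipe("none", 288.15, 7.0))
        assert comp.totals == {}

    def test_unmapped_salt_rejected(self):
        with pytest.raises(RecipeError):
            recipe_to_composition(Recipe(
                "x", 288.15, 7.0, salts_g_per_L=[("FeSO4·7H2O", 1.0)]))


class TestMedium:
    def test_printed_recipe_totals(self, medium):
        totals = medium.composition.totals
        # 50 mmol acid + sulfate from Na2SO4, MgSO4.7H2O, (NH4)2SO4
        assert totals["S(VI)"] == pytest.approx(0.07005, abs=2e-4)
        assert totals["N(-III)"] == pytest.approx(1.97e-3, abs=2e-5)
        assert totals["S(-II)"] == pytest.approx(2e-3, abs=1e-12)
        assert totals["C(IV)"] == pytest.approx(1e-2, abs=1e-12)
        assert medium.T == pytest.approx(288.15)
        assert medium.pH == 1.0

    def test_medium_speciates_to_convergence(self, medium_solution):
        assert medium_solution.converged


class TestFrasassi:
    def test_charge_balance_closure(self):
        sc = frasassi_insitu(0.5, 24.0)
        sol = speciate(sc.composition)
        db = default_database()
        imbalance = sum(st.molality * db[n].charge
                        for n, st in sol.species.items())
        assert sol.log_activity("H+") == -0.5
        assert abs(imbalance) < 1e-9 * sol.molality("H+")

    def test_lower_ph_needs_more_sulfate(self):
        s0 = frasassi_insitu(0.0, 24.0).composition.totals["S(VI)"]
        s1 = frasassi_insitu(1.0, 24.0).composition.totals["S(VI)"]
        assert s0 > s1

    def test_out_of_range_inputs_warn(self):
        with pytest.warns(UserWarning):
            frasassi_insitu(2.0, 24.0)
        with pytest.warns(UserWarning):
            frasassi_insitu(0.5, 50.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_closure_on_random_draws(self, seed):
        rng = np.random.default_rng(seed)
        pH = float(rng.uniform(0.0, 1.0))
        ppmv = float(rng.uniform(15.0, 33.0))
        sc = frasassi_insitu(pH, ppmv)
        sol = speciate(sc.composition)
        db = default_database()
        imbalance = sum(st.molality * db[n].charge
                        for n, st in sol.species.items())
        assert abs(imbalance) < 1e-9 * sol.molality("H+")


class TestRandomScenario:
    def test_deterministic_given_seed(self):
        a, b = random_scenario(42), random_scenario(42)
        assert a.composition == b.composition
        assert a.seed == 42

    def test_distinct_seeds_differ(self):
        assert random_scenario(1).composition != random_scenario(2).composition

    def test_draws_respect_bounds(self):
        for seed in range(50):
            sc = random_scenario(seed)
            assert 273.15 <= sc.T <= 323.15
            assert 0.0 <= sc.pH <= 7.0
            for v in sc.composition.totals.values():
                assert 1e-6 <= v <= 1e-1

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            random_scenario(0, {"pH": (3.0, 3.0)})


def test_scenario_toml_round_trip(tmp_path, medium):
    text = dump_scenario(medium)
    p = tmp_path / "sc.toml"
    p.write_text(text)
    back = load_scenario(p)
    assert back.pH == medium.pH
    assert back.T == pytest.approx(medium.T)
    for k, v in medium.composition.totals.items():
        assert back.composition.totals[k] == pytest.approx(v, rel=1e-12)
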