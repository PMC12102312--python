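# sulfotherm

Gibbs-energy bioenergetics of aqueous sulfur reactions: revised-HKF
standard states at 1 bar, EQ3/6-style B-dot speciation at fixed pH,
catabolic reaction energetics, and inverse design of culture media that
match a field site's energy yield.

## The problem

Thermodynamics can predict microbial catabolisms before anyone
cultivates the organism that runs them: any redox reaction that is
exergonic under in-situ conditions is a candidate metabolism.  Sulfur
comproportionation,

    3 H2S + SO4^2- + 2 H+  =  4 S0 + 4 H2O,

is exergonic in cold, extremely acidic, sulfide- and sulfate-rich
settings — the environment of the pH 0–1 "snottite" biofilms of the
Frasassi cave system (13.4 °C, 15–33 ppmv H₂S in the cave air, sulfate
from sulfuric acid).  Designing an enrichment medium for such an
organism means reproducing not the site's chemistry but its *energy*:
choosing concentrations so the medium's ΔG_r for the target reaction
equals the field value.

`sulfotherm` implements that entire calculation chain for
geomicrobiologists and culture designers:

1. **Standard states** — ΔG°(T) of aqueous species via the revised
   Helgeson–Kirkham–Flowers (HKF) equations of state at 1 bar (the
   pressure block drops out identically); gases, sulfur and liquid
   water via Maier–Kelley heat capacities.  ΔG°_r = Σ νᵢΔG°ᵢ and
   log K = −ΔG°_r/(RT ln 10).
2. **Speciation** — totals are distributed by mass action at the
   *measured* pH (no charge-balance closure), with B-dot extended
   Debye–Hückel activity coefficients,
   log γᵢ = −A zᵢ²√I/(1 + åᵢB√I) + Ḃ I, iterated to a self-consistent
   ionic strength.  a(S⁰) = a(H₂O) = 1, a(H⁺) = 10^−pH.
3. **Energetics** — ΔG_r = ΔG°_r + RT ln Q with
   Q = Π aᵢ^νᵢ, normalized per mole of reaction, per electron (6 e⁻
   for comproportionation) and per mole of S⁰ produced (4).
4. **Design** — 1-D bracketed root-finding of one free medium
   parameter (e.g. total sulfide) against a target ΔG_r.

## Worked example

```python
from sulfotherm import (comproportionation, comproportionation_medium,
                        delta_G_r, speciate)

rxn = comproportionation()                 # 3 H2S + SO4-2 + 2 H+ = 4 S0 + 4 H2O
medium = comproportionation_medium()       # pH 1, 15 C, 2 mM sulfide recipe
sol = speciate(medium.composition)
res = delta_G_r(rxn, medium)
print(f"I = {sol.ionic_strength:.3f} mol/kg")
print(f"dG0r = {res.dG0r/1e3:.1f} kJ/mol, logK = {res.log10K:.2f}, "
      f"logQ = {res.log10Q:.2f}")
print(f"dGr = {res.dGr/1e3:.1f} kJ/mol -> energy yield {res.yield_/1e3:.1f} kJ/mol")
```

prints

```
I = 0.155 mol/kg
dG0r = -120.4 kJ/mol, logK = 21.83, logQ = 12.36
dGr = -52.2 kJ/mol -> energy yield 52.2 kJ/mol
```

i.e. in the cultivation medium (70 mmol/kg total sulfate, three
quarters of it as HSO₄⁻ at pH 1, 2 mmol/kg sulfide at 15 °C) sulfur
comproportionation yields ≈52 kJ per mole of reaction — an energy
supply comparable to classic chemolithotrophic metabolisms.  The same
API evaluates the Frasassi field scenario
(`frasassi_insitu(pH, h2s_ppmv)`), sweeps energy landscapes over T,
pH and activities, screens the six sulfate-reduction/ammonium-oxidation
couples (all endergonic in this medium: nothing but sulfide can reduce
sulfate there), and solves the inverse medium-design problem
(`solve_design`).

The same operations are available from the shell:

```sh
sulfotherm scenarios list
sulfotherm speciate comproportionation_medium
sulfotherm suite
```

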