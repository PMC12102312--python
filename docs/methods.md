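# Methods

This note documents the models, numerical choices and stated
approximations behind `sulfotherm`, and what the synthetic scenarios
do and do not establish about real systems.

## Standard-state model

Aqueous species follow the revised Helgeson–Kirkham–Flowers (HKF)
equations of state evaluated at P = Pr = 1 bar, where every
(P − Pr) term — the a₁–a₄ pressure block — vanishes identically:

    ΔG°(T) = ΔG°f − S°(T−Tr)
             − c₁[T ln(T/Tr) − T + Tr]
             − c₂[((1/(T−Θ) − 1/(Tr−Θ))((Θ−T)/Θ))
                  − (T/Θ²) ln(Tr(T−Θ)/(T(Tr−Θ)))]
             + ω(1/ε(T) − 1/ε(Tr)) + ω Y(Tr)(T−Tr)

with Θ = 228 K, Tr = 298.15 K, ε the dielectric constant of water and
Y = (1/ε²)∂ε/∂T.  The Born coefficient ω is held at its 25 °C value:
below 100 °C at 1 bar the g-function correction to ω for charged
species is well under 0.1 kJ/mol, which is far below the other
uncertainties of this analysis; this is the engine's stated
approximation.  At exactly Tr the expression returns the database
formation energy, and −∂ΔG°/∂T at Tr returns S° analytically (the
suite verifies both, the latter by centered differences with
δ = 0.01 K at 0.5 % relative tolerance).

Gases, crystalline sulfur and liquid water use Maier–Kelley heat
capacities Cp = a + bT + c/T² with closed-form integrals

    ΔG°(T) = ΔG°f − S°(T−Tr) + ∫Cp dT − T ∫(Cp/T) dT.

Liquid water is carried with a constant Cp of 75.3 J/mol/K (b = c = 0),
accurate to ~1 % over 0–100 °C; at the ≤12 K excursions from 25 °C used
here the induced error in ΔG°(H₂O) is < 20 J/mol.

Validity is restricted to 0–100 °C at 1 bar; temperatures outside that
range raise errors rather than extrapolate, since every application of
the package sits at 13.4–15 °C.

## Species database

The packaged CSV covers exactly the species this analysis consumes
(sulfide/sulfate systems, the ammonium-oxidation products, medium
cations, carbonate) with 25 °C/1 bar formation properties, HKF
temperature blocks (c₁, c₂, ω) for aqueous species, Maier–Kelley
coefficients otherwise, and B-dot ion-size parameters.  Values are a
hand-compiled SUPCRT-lineage subset, stored in J-based units with the
conventional scale factors removed and calorie sources converted with
4.184 exactly.  The a₁–a₄ columns are retained for future pressure
work but are inert at 1 bar.  Internal consistency is what the tests
pin down: the implied equilibrium constants at 25 °C are
pK₁(H₂S) = 6.99, pK₂(H₂SO₄) = 1.98, pKa(NH₄⁺) = 9.24,
pK₁(CO₂) = 6.34, pKw = 14.00, log K_H(H₂S) = −0.97,
log K_H(N₂) = −3.19, log K_H(CO₂) = −1.47 — all at their accepted
values.  Different database snapshots circulating in the field differ
at the 0.1 kJ/mol level in formation energies; results inherit that
uncertainty.

## Solvent and activity model

Water's dielectric constant uses the Bradley–Pitzer (1979)
correlation (the EQ3/6-lineage choice; ε(25 °C) = 78.38), density the
Kell (1975) 1-atm polynomial, and the Debye–Hückel slopes their
standard definitions from ε and ρ (A(25 °C) = 0.510,
B(25 °C) = 0.328 Å⁻¹).  The Born Y function is the analytic
temperature derivative of the Bradley–Pitzer form.  All coefficients
ship as a CSV resource and can be overridden by path.

Activity coefficients follow the B-dot extended Debye–Hückel model,

    log₁₀ γᵢ = −A zᵢ² √I / (1 + åᵢ B √I) + Ḃ I,

with Ḃ(T) linearly interpolated from the standard table
{0 °C: 0.0374, 25 °C: 0.0410, 60 °C: 0.0438, 100 °C: 0.0460} and å
from a Kielland-style table stored with the species data.  Neutral
species take γ = 1: the CO₂-type salting-out correction is omitted,
an approximation worth ≲1 % in activity below I ≈ 0.5 mol/kg, which
bounds every scenario shipped here (the medium converges at
I = 0.155 mol/kg).

## Speciation

pH is treated as a *measurement*, not a model output: a(H⁺) = 10^−pH
exactly, and no charge balance is imposed on measured compositions.
Each component's total is distributed among its species (SO₄²⁻/HSO₄⁻,
H₂S/HS⁻, NH₄⁺/NH₃, CO₂/HCO₃⁻) by mass action using log K(T) from the
standard-state engine and the current activity coefficients; ionic
strength is converged by fixed-point iteration (relative tolerance
1e-10, cap 100 iterations, 0.5 damping if the iterate oscillates),
and non-convergence is flagged on the result rather than raised or
hidden.  The free proton pool implied by the pH (m = a/γ) and the
corresponding hydroxide are included in the ionic strength — at pH 1
the proton is the single largest contributor and excluding it would
corrupt every γ.  Mass balance per component is exact by
construction and is audited to 1e-12 relative on a thousand seeded
random compositions.

Phosphate is tracked as an inert total (its sodium counts toward the
cation budget) but excluded from speciation and ionic strength;
likewise trace elements, vitamins and resazurin.  At their ≤ mmol
levels the effect on I is below 1 %.

Gas–solution coupling is Henry's law with unit fugacity coefficient
at the ~1.013 bar cave/headspace pressure: a(aq) = K_dissolution(T)·p,
with ppmv converting as p = ppmv × 1e-6 × 1.013 bar.

## Scenarios

Two scenarios are built entirely from printed protocol/field values:

* **Cultivation medium** — the basal-salt recipe (Na₂SO₄,
  MgSO₄·7H₂O, CaCl₂·2H₂O, KCl, (NH₄)₂SO₄, Na₂HPO₄ in 50 mM H₂SO₄)
  converted salt-by-salt through an explicit dissociation map, plus
  10 mM bicarbonate and 2 mM sulfide amendments; pH 1, 15 °C, 80/20
  N₂/CO₂ headspace.  Molarity ≈ molality (1 L ≈ 1 kg water) at these
  dilutions.  Total S(VI) computes to 70.05 mmol/kg.
* **Field site** — 13.4 °C (the cave environment; the 15 °C
  incubation temperature plays a different role and both are kept),
  pH in 0–1, H₂S(g) in 15–33 ppmv.  Sulfate is "inferred from pH":
  total S(VI) is solved by bracketed root-finding so that the
  sulfuric-acid anions exactly charge-balance the pH-implied proton
  pool.  Dissolved sulfide then follows from gas equilibrium.

Because the field ranges are printed as ranges, the field energy is
reported as an envelope over the four (pH, ppmv) corners plus the
midpoint rather than as a single number.

The seeded random-scenario generator draws T in 0–50 °C, pH in 0–7,
component totals log-uniformly in 1e-6–1e-1 mol/kg and H₂S(g) in
0–100 ppmv — the same structure as the field data, spanning it with
margin.  It exists for property testing (mass balance, monotonicity,
determinism); passing on it shows the *solver* is correct over that
envelope, not that any particular natural water is described well.
Real snottite fluids contain Fe, Al and other solutes this database
omits, and at pH 0 the field-site closure drives I above the B-dot
comfort zone (~1 mol/kg), where computed γ carry extra uncertainty.

## Energetics and the exclusion screen

ΔG_r = ΔG°_r + RT ln Q is carried as an exact identity (re-asserted on
every stored result), with Q from log-activity sums.  Electron counts
derive from formal oxidation states (S: −2/0/+6; N: −3/0/+3/+5); for
comproportionation, where the net element change is zero, atoms are
paired across the reaction in oxidation-state order and upward
transfers summed, giving the conventional 6 e⁻.  A per-reaction
override exists for unusual conventions.

The exclusion screen evaluates the 2×3 grid of sulfate reduction
(→ S⁰ or H₂S) against ammonium oxidation (→ N₂, NO₂⁻, NO₃⁻) in the
medium at 15 °C.  These six stoichiometries are re-derived from
half-reactions (they are a reconstruction of the natural product
grid, balanced exactly).  Dissolved N₂ takes its activity from the
0.8 bar headspace; NO₂⁻ and NO₃⁻, absent from the medium, are
assigned a trace activity of 1e-6 molal — a detection-limit
convention, adjustable via `trace_log_activity`.  Five of the six
reactions are endergonic by tens to hundreds of kJ/mol regardless of
that convention; the SO₄²⁻ + 2 NH₄⁺ → S⁰ + N₂ couple is genuinely
near equilibrium (≈ +0.6 kJ/mol here) and its sign is sensitive to
database choice at the ~1 kJ/mol level — a caveat worth keeping in
mind when citing the screen.

## The headline energy and its basis

The medium scenario yields 52.2 kJ per mole of reaction
(8.7 kJ/mol e⁻, 13.1 kJ/mol S⁰) — matching the 52 kJ/mol figure
reported for this system, whose normalization basis is not stated;
the per-reaction basis is the one that matches.  The field-site
envelope computed with strictly gas-equilibrated sulfide
(a(H₂S) ≈ 3×10⁻⁶ at 24 ppmv) is 5–22 kJ/mol per reaction — much
smaller, because µmolal sulfide costs ~16.5 kJ per decade (3 RT ln 10).
Since the medium was, by design, energy-matched to the site, the
52 kJ/mol site figure corresponds to a mmolal-scale dissolved-sulfide
activity (for instance, reading ppmv as an aqueous mole fraction gives
~1.3 mmol/kg and 52–63 kJ/mol over the envelope) rather than to
Henry-law equilibrium with 15–33 ppmv of cave air.  The package
reports both routes and leaves the discrepancy visible rather than
tuning either.

## Inverse design

`solve_design` adjusts one free parameter (a component total, pH, or
T) by Brent's method until ΔG_r on a declared basis (per reaction,
per electron, per S⁰ — the basis tag is mandatory precisely because
headline numbers in this field often omit it) hits a target within
1 J/mol.  Non-bracketing bounds are reported as errors, never
clamped.  The self-consistency round trip — using the shipped
medium's own ΔG_r as the target recovers its 2 mmol/kg sulfide to
1e-6 relative — is part of the acceptance suite.

## Problem sizes and determinism

All computations are closed-form or low-dimensional root-finds; the
full test suite (including the thousand-scenario speciation audit)
runs in a few seconds on one CPU, and `scripts/acceptance.py` in
seconds.  Every stochastic element (random scenarios, the
mass-balance audit) is seeded; speciation itself is a fixed
deterministic iteration, so identical inputs give bit-identical
outputs.

## Module map

* `formula`, `database`, `reactions`, `recipe` — formula parsing,
  molar masses, the species CSV, reaction parsing/validation/electron
  counting, recipe → composition (the thermodynamic-database layer).
* `water`, `hkf` — solvent correlations and standard-state engine.
* `speciation` — B-dot model and the fixed-pH solver.
* `energetics` — quotients, ΔG_r, landscapes, the exclusion screen.
* `scenarios` — fixtures, TOML I/O, random generator.
* `design` — the inverse problem.  `cli` — thin click wrappers.
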