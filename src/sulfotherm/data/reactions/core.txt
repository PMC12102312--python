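# Core reaction library. One reaction per line: "label: a A + b B = c C".
# Coefficients are exact rationals; reactants left, products right.

# sulfur comproportionation (the catabolic reaction under study)
comproportionation: 3 H2S + 1 SO4-2 + 2 H+ = 4 S0 + 4 H2O

# gas dissolution (Henry's-law) equilibria
h2s_dissolution: 1 H2S(g) = 1 H2S
n2_dissolution: 1 N2(g) = 1 N2
co2_dissolution: 1 CO2(g) = 1 CO2

# acid-base pairs used by the speciation solver
h2s_ionization: 1 H2S = 1 H+ + 1 HS-
hso4_ionization: 1 HSO4- = 1 H+ + 1 SO4-2
nh4_ionization: 1 NH4+ = 1 H+ + 1 NH3
co2_hydration_ionization: 1 CO2 + 1 H2O = 1 H+ + 1 HCO3-
water_ionization: 1 H2O = 1 H+ + 1 OH-
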