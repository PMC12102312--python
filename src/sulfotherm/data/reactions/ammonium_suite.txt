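# Sulfate reduction coupled to ammonium oxidation: the 2x3 product grid
# (S products: S0, H2S; N products: N2, NO2-, NO3-), re-derived from
# half-reactions and balanced exactly. Used by the exclusion screen that
# asks whether any reductant other than sulfide can reduce sulfate in
# the cultivation medium.
amox_S0_N2: 1 SO4-2 + 2 NH4+ = 1 S0 + 1 N2 + 4 H2O
amox_H2S_N2: 3 SO4-2 + 8 NH4+ = 3 H2S + 4 N2 + 12 H2O + 2 H+
amox_S0_NO2: 1 SO4-2 + 1 NH4+ = 1 S0 + 1 NO2- + 2 H2O
amox_H2S_NO2: 3 SO4-2 + 4 NH4+ = 3 H2S + 4 NO2- + 4 H2O + 2 H+
amox_S0_NO3: 4 SO4-2 + 3 NH4+ + 2 H+ = 4 S0 + 3 NO3- + 7 H2O
amox_H2S_NO3: 1 SO4-2 + 1 NH4+ = 1 H2S + 1 NO3- + 1 H2O
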