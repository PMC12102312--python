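component,species,role,reaction
S(VI),SO4-2,reference,
S(VI),HSO4-,secondary,hso4_ionization
S(-II),H2S,reference,
S(-II),HS-,secondary,h2s_ionization
N(-III),NH4+,reference,
N(-III),NH3,secondary,nh4_ionization
C(IV),CO2,reference,
C(IV),HCO3-,secondary,co2_hydration_ionization
Na,Na+,reference,
K,K+,reference,
Mg,Mg+2,reference,
Ca,Ca+2,reference,
Cl,Cl-,reference,
N(0),N2,reference,
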