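salt,component,count
Na2SO4,Na,2
Na2SO4,S(VI),1
MgSO4·7H2O,Mg,1
MgSO4·7H2O,S(VI),1
CaCl2·2H2O,Ca,1
CaCl2·2H2O,Cl,2
KCl,K,1
KCl,Cl,1
(NH4)2SO4,N(-III),2
(NH4)2SO4,S(VI),1
Na2HPO4,Na,2
Na2HPO4,phosphate,1
NaHCO3,Na,1
NaHCO3,C(IV),1
Na2S·9H2O,Na,2
Na2S·9H2O,S(-II),1
NaCl,Na,1
NaCl,Cl,1
H2SO4,S(VI),1
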