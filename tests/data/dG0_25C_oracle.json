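{
 "amox_S0_N2": -27175.08,
 "amox_H2S_N2": 11811.432,
 "amox_S0_NO2": 317331.296,
 "amox_H2S_NO2": 1389836.936,
 "amox_S0_NO3": 1223204.952,
 "amox_H2S_NO3": 447905.568,
 "comproportionation": -120511.752,
 "h2s_dissolution": 5518.696,
 "n2_dissolution": 18187.848,
 "co2_dissolution": 8384.736,
 "h2s_ionization": 39886.072,
 "hso4_ionization": 11296.8,
 "nh4_ionization": 52747.688,
 "co2_hydration_ionization": 36216.704,
 "water_ionization": 79885.112
}
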