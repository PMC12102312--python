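parameter,value,note
bp_U1,342.79,Bradley-Pitzer (1979) dielectric-constant correlation
bp_U2,-5.0866e-3,
bp_U3,9.4690e-7,
bp_U4,-2.0525,
bp_U5,3115.9,
bp_U6,-182.89,
bp_U7,-8032.5,
bp_U8,4.2142e6,
bp_U9,2.1417,
kell_n0,999.83952,Kell (1975) liquid-water density at 1 atm
kell_n1,16.945176,
kell_n2,-7.9870401e-3,
kell_n3,-46.170461e-6,
kell_n4,105.56302e-9,
kell_n5,-280.54253e-12,
kell_d1,16.879850e-3,
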