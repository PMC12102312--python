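T_C,bdot
0,0.0374
25,0.0410
60,0.0438
100,0.0460
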