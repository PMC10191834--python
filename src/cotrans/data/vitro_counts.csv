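label,dose,r0,r1,r2,r3
1e10,1e10,14,77,184,1475
5e10,5e10,5,9,52,1707
5e11,5e11,0,0,0,1791
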