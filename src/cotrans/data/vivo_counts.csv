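label,dose,r0,r1,r2,r3
ACC,,0,0,20,3948
MC,,0,7,12,4319
PFC,,0,3,13,4443
SSC,,0,5,7,4712
VI,,0,4,15,4397
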