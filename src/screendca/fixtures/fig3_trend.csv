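stratum,period,n,successes
eca_negative,P1,195,15
eca_negative,P2,314,49
eca_negative,P3,71,14
eca_positive,P1,118,42
eca_positive,P2,235,93
eca_positive,P3,80,31
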