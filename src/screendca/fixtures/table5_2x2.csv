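tp,fp,fn,tn
166,267,78,502
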