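gene,risk_group,wild_type,mutated
TSC1,low,177,28
TSC1,high,196,11
ERBB3,low,175,30
ERBB3,high,192,15
FGFR3,low,163,42
FGFR3,high,184,23
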