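label,expected
OCT3/4,up
SOX2,up
NANOG,up
GDF3,up
REX1,up
FGF4,up
ESG1,up
DPPA2,up
DPPA4,up
hTERT,up
SALL4,up
SSEA-3,up
SSEA-4,up
TRA-1-81,up
ALP,up
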