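label,expected
BDNF,up
FKBP5,up
IGF2,up
DLX5,up
DLX6,up
SGK1,up
MPP1,up
GAMT,up
FXYD1,up
UBE3A,down
GRID1,down
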