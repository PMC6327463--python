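'on':
- CMYC
- KLF4
- OCT3/4
- SOX2
'off': []
locked_on: []
locked_off: []
activation: elliott
tolerance: 0.001
max_iterations: 1000
overtraining_check: true
seed: 0
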