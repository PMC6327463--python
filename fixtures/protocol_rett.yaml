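'on':
- SOX2
'off':
- LET7
locked_on: []
locked_off:
- MECP2
activation: elliott
tolerance: 0.001
max_iterations: 1000
overtraining_check: true
seed: 0
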