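# Absorbing (u = 0) switching game used for the fixation sweeps
environment:
  type: discrete
  p_plus: 0.01
  p_minus: 0.01
game:
  N: 50
  beta: 0.5
  b: 0.5
  c: 0.9
  u: 0.0
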