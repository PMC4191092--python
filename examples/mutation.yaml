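# Mutation-selection model: switching game with u = 0.02
environment:
  type: discrete
  p_plus: 1.0e-3
  p_minus: 1.0e-3
game:
  N: 50
  beta: 0.5
  b: 0.5
  c: 0.9
  u: 0.02
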