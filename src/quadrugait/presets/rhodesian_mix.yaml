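# Mixed-breed (50% Rhodesian ridgeback) at a slow walk.
name: rhodesian_mix
morphology:
  mF_prime: 0.63
  lB: 0.63
  lHmax_prime: 0.91
  lFmax_prime: 0.75
task:
  U_H_prime: 0.34
  D_prime: 1.3
  c1D_prime: 3.0e-3
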