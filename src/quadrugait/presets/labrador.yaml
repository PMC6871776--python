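# Labrador retriever at a running trot.
name: labrador
morphology:
  mF_prime: 0.66
  lB: 0.52
  lHmax_prime: 0.86
  lFmax_prime: 0.72
task:
  U_H_prime: 1.15
  D_prime: 2.0
  c1D_prime: 3.0e-3
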