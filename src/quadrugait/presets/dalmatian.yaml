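# Dalmatian at a moderate walk: the force-rate calibration case.
name: dalmatian
morphology:
  mF_prime: 0.61
  lB: 0.61
  lHmax_prime: 0.89
  lFmax_prime: 0.79
task:
  U_H_prime: 0.39
  D_prime: 1.21
  c1D_prime: 3.0e-3
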