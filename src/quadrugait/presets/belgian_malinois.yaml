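# Belgian Malinois speed-sweep morphology; supply U_H_prime per run.
# Stride length defaults to the breed regression D' = 1.04 + 1.36 U_H'.
name: belgian_malinois
morphology:
  mF_prime: 0.63
  lB: 0.48
  lHmax_prime: 1.01
  lFmax_prime: 0.92
task:
  U_H_prime: null
  c1D_prime: 3.0e-3
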