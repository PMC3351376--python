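# Default population-state-model parameters: nominal A<->N transition
# probabilities and per-state P/N/Z emission distributions, as estimated
# from annotated multi-colored yeast chemostat evolution experiments.
p_AN0: 0.154
p_NA0: 0.079
e_A:
  N: 0.102
  Z: 0.150
  P: 0.748
e_N:
  N: 0.434
  Z: 0.337
  P: 0.229
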