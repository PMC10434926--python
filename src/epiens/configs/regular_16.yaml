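network:
  family: regular
  n: 1000
  k: 3
  seed: 13
outbreak: {}
observation:
  model: random
  q_S: 0.016
  q_I: 0.09
  q_R: 0.033
inference:
  K: 100
  beta_lo: 0.1
  beta_hi: 0.3
  p0: 0.01
  D: 3.0
methods:
- ens
- dmp1
- dmp2
- degree
- contact
replicates: 20
seed: 0
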