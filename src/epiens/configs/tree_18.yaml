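network:
  family: tree
  branching: 5
  depth: 4
outbreak: {}
observation:
  model: random
  q_S: 0.02
  q_I: 0.1
  q_R: 0.04
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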