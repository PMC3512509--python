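# Calibrate the 3-reaction synthetic pathway (dynamic variant) with eSS.
problem:
  kind: toy_network
  n_reactions: 3
  variant: dynamic
  network_seed: 0
  data_seed: 0
  noise_cv: 0.0
solver: ess
seed: 1
ess:
  max_evals: 200000
  target_cost: 1.0e-6
  local_solver: dhc
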