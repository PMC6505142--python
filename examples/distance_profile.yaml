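# Rejection-rate curve vs distance between the QTL and the distal marker on
# the synthetic LD-decay chromosome (hump shape: rises at short lags, falls
# back to alpha as the markers decouple).
experiment: distance_profile
master_seed: 1
params:
  lags_bp: [50000, 150000, 300000, 600000, 1200000, 2400000]
  n_grid: [10000, 100000]
  phi_grid: [0.005, 0.01]
  maf: 0.3
  decay_lambda: 300000
  replicates: 500
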