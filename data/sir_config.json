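{
  "tau": 0.45,
  "eta": 0.13,
  "d": 1.5,
  "lambda": 0.1,
  "lambda_mode": "per_degree",
  "alpha": 0.125,
  "nu": 0.1,
  "dt": 0.02,
  "dx": 0.55,
  "t_end": 20.0,
  "sample_every": 10,
  "seed_vertex": "v18",
  "seed_amount": 1e-06,
  "s0": 0.25,
  "populated": [
    "v1",
    "v15",
    "v17",
    "v18",
    "v2",
    "v3",
    "v4",
    "v6",
    "v7",
    "v8",
    "v9"
  ],
  "auc_scale": 1.0
}
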