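{
  "kind": "lattice",
  "M": 51, "N": 51, "n": 500,
  "x0": [26, 26],
  "food_sources": [[41, 26], [11, 26]],
  "D": 10.0, "gamma": 0.001, "A_dep": 1.0, "sigma_decay": 1.0,
  "epsilon": 0.001, "sense_threshold": 0.002, "weber_fraction": 0.0,
  "dt": 0.001, "dx": 1.0, "T_max": 300, "seed": 1
}
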