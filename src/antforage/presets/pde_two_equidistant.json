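{
  "kind": "continuum",
  "Lx": 30.0, "Ly": 30.0,
  "x0": [15.0, 15.0],
  "food_sources": [[24.0, 15.0], [6.0, 15.0]],
  "alpha": 1.0, "chi": 1.0, "nu": 1.0,
  "Omega_pq": 1.0, "Omega_qp": 1.0,
  "D": 10.0, "gamma": 0.001, "A_dep": 1.0,
  "h": 0.5, "dt": 0.01, "delta_width": 1.0
}
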