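{
  "label": "WT",
  "act_v_half": -29.9,
  "act_k": 5.7,
  "fast_v_half": -86.6,
  "fast_k": 5.6,
  "slow_v_half": -61.1,
  "slow_k": 13.7,
  "tau_h_depol": 1.7,
  "tau_h_hyper": 102.3,
  "slow_r_in": 0.2,
  "g_max": 100.0,
  "tau_m": 0.1,
  "tau_h_floor": 0.05,
  "tau_s": 5000.0
}
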