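{
  "label": "T1596I",
  "act_v_half": -26.6,
  "act_k": 5.5,
  "fast_v_half": -71.2,
  "fast_k": 7.6,
  "slow_v_half": -60.9,
  "slow_k": 11.7,
  "tau_h_depol": 2.9,
  "tau_h_hyper": 28.7,
  "slow_r_in": 0.2,
  "g_max": 100.0,
  "tau_m": 0.1,
  "tau_h_floor": 0.05,
  "tau_s": 5000.0
}
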