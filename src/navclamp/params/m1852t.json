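{
  "label": "M1852T",
  "act_v_half": -27.6,
  "act_k": 6.3,
  "fast_v_half": -72.5,
  "fast_k": 9.1,
  "slow_v_half": -67.5,
  "slow_k": 12.9,
  "tau_h_depol": 3.4,
  "tau_h_hyper": 106.3,
  "slow_r_in": 0.2,
  "g_max": 100.0,
  "tau_m": 0.1,
  "tau_h_floor": 0.05,
  "tau_s": 5000.0
}
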