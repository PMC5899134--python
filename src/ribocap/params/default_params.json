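{
  "a_plus_M": 0.0001,
  "a_minus_M": 200.0,
  "b0_M": 1.0,
  "R_total": 2500.0,
  "monitor": {
    "name": "monitor",
    "rbs_strength": 1.0,
    "mrna_conc": 900.0,
    "length_bp": 720,
    "gamma": 1.0
  }
}
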