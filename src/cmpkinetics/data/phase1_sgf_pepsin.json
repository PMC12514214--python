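{
  "v0": 1.0,
  "pulse1": {"n": 0.0116, "t_plus": 187.5, "sigma": 11.0},
  "pulse2": {"n": 0.015, "t_plus": 300.0, "sigma": 35.15}
}
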