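{
  "v0": 1.0,
  "pulse1": {"n": 0.0135, "t_plus": 416.8, "sigma": 11.0},
  "pulse2": {"n": 0.0426, "t_plus": 540.0, "sigma": 37.86}
}
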