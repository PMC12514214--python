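{
  "v0": 197.4,
  "pulse3": {"n": 0.0141, "t_plus": 193.5, "sigma": 37.0},
  "v4": 122.3,
  "t4": 141.7,
  "v_inf": 55.5,
  "breakpoint": 147.0
}
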