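{
  "v0": 217.45,
  "gauss1": {"n": 0.000423, "t_plus": 187.5, "sigma": 11.0},
  "gauss2": {"n": 0.00017, "t_plus": 300.0, "sigma": 35.15},
  "gauss3": {"n": 0.0141, "t_plus": 510.0, "sigma": 37.16},
  "rc1": 0.0032,
  "nx": 1.5,
  "rc2": 0.005,
  "rc3": 0.1533,
  "swell_start": 300.0,
  "surface_shrink_start": 424.0,
  "degradation_start": 536.0,
  "dt": 0.25,
  "t_end": 2400.0
}
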