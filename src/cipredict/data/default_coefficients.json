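{
  "label": "published",
  "beta0": 0.84,
  "beta1": 0.012,
  "beta2": -0.0094,
  "beta3": 0.0059,
  "se0": 0.18,
  "se1": 0.0015,
  "se2": 0.0025,
  "se3": 0.0026
}
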