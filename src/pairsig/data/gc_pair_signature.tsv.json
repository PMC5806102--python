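{
  "cutoff": -0.154,
  "horizon": 60.0,
  "n_pairs": 7
}
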