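{
  "birth_rate": 1.0,
  "death_rate": 0.0,
  "crown_age": null,
  "target_n": 12,
  "rate_mean": 0.01,
  "rate_autocorr_sd": 0.1,
  "seq_length": 1500,
  "seed": 0,
  "retry_cap": 1000
}
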