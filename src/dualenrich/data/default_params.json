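{
  "mu_specialist": 0.25,
  "death_rate": 0.089051513671875,
  "duration": 48.0,
  "carrying_capacity": 1000000000.0,
  "transfer_fraction": 0.1
}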