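{
  "config_hash": "17e7af4b0ed66225",
  "log": [
    "simulated cohort of 9 individuals (seed 11)",
    "background slopes for temperatures: [10.0, 16.0, 21.0]",
    "alpha = -0.2155 (R^2 0.363, n 27, strata ('kind', 'temperature'))",
    "cutoffs: 16: (1.75, 2.6, 3.45) (table_packaged); 10: (2.59, 3.68, 4.77) (table_packaged); high: (3.35, 4.2, 5.05) (table_packaged)"
  ]
}
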