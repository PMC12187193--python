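{
  "config_hash": "4c73b77bc50bc4bf",
  "log": [
    "simulated cohort of 3 individuals (seed 7)",
    "background slopes for temperatures: [10.0, 16.0, 21.0]",
    "alpha = -0.2002 (R^2 1.000, n 9, strata ('kind', 'temperature'))",
    "cutoffs: 16: (1.75, 2.6, 3.45) (table_packaged); 10: (2.59, 3.68, 4.77) (table_packaged); high: (3.35, 4.2, 5.05) (table_packaged)"
  ]
}
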