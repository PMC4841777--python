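{
  "subcommand": "simulate",
  "seed": 1,
  "n_cells": 200,
  "genotype": "wild_type",
  "model_params": {
    "production_coeff": 1.0,
    "production_exponent": 1.5,
    "exit_threshold": 2000.0,
    "degradation_fraction": 0.1,
    "commitment_size": 195.0,
    "sensed_quantity": "per_dna_ratio",
    "decrement_mode": "geometric",
    "unit_mode": false,
    "max_rounds": 5,
    "null_exit_threshold": 220.0,
    "overexpression_supplement": 0.0
  },
  "growth_config": {
    "light_hours": 14.0,
    "size_doubling_time": 4.0,
    "growth_noise_cv": 0.15,
    "seed": 1
  }
}
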