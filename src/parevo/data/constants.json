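{
  "par1_genetic_length_morgans": 0.2285,
  "target_mean_cmmb": 9.01,
  "trio_rate_per_year": 6.4e-10,
  "generation_times_years": {
    "chimpanzee": 25,
    "bonobo": 25,
    "gorilla": 19,
    "orangutan": 26
  },
  "recomb_bin_cuts_cmmb": [4.25, 11.29],
  "window_bp": 10000,
  "min_callable_sites": 2500,
  "bootstrap_reps": 100,
  "par1_length_bp": 2700000,
  "crossover_window_bp": 40000,
  "crossover_local_rate_pg": 3.3e-8,
  "background_male_rate_pg": 9.6e-9,
  "autosomal_pairwise_divergence": {
    "human_chimpanzee": 0.0137,
    "human_gorilla": 0.0175,
    "human_orangutan": 0.034
  }
}
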