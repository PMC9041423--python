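# A small synthetic fall-run scenario: cool 15-km river, autumn spawning,
# mid-winter emergence, upstream redds and rearing.
seed: 2
river:
  river_length_km: 15
  mean_annual_temp: 12.0
monitors:
  spacing_km: 5
populations:
  - name: fall
    run_type: fall
    scenario:
      arrival_mean: 250
      spawn_mean: 290
      emergence_mean: 30
      redd_mean_km: 12
      redd_sd_km: 2
      rearing_mean_km: 10
      rearing_sd_km: 3
n_draws: 200
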