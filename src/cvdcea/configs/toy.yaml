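# Small configuration for quick runs: reduced survey size and few
# Monte Carlo draws.  Analysis settings otherwise match the defaults.
schema: cvdcea/run/v1
seed: 1
output_dir: results/toy
generator:
  n_per_cell: 80
economics:
  discount_rate: 0.03
  threshold: 50000
  metric: DALY
coverage:
  gp_attendance: 0.85
  assessment_participation: 0.60
psa:
  enabled: true
  n_draws: 50
  max_frontier_packages: 5
analysis:
  statin_price: australia
  behaviour_effectiveness_scale: 0.01
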