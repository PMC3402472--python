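# Full demonstration configuration: the built-in intervention catalogue
# with the synthetic-epidemiology defaults, 3% discounting, a
# $50,000/DALY decision threshold and probabilistic uncertainty
# analysis.  Counselling-based behaviour-change interventions (dietary
# advice, lifestyle program, community heart health program) realise 1%
# of their trial efficacy in sustained routine delivery, encoding the
# poor persistence of counselling-induced risk-factor change.
schema: cvdcea/run/v1
seed: 1
output_dir: results/full
generator:
  n_per_cell: 250
economics:
  discount_rate: 0.03
  threshold: 50000
  metric: DALY
coverage:
  gp_attendance: 0.85
  assessment_participation: 0.60
psa:
  enabled: true
  n_draws: 200
  max_frontier_packages: 8
analysis:
  statin_price: australia
  behaviour_effectiveness_scale: 0.01
  trend_enabled: true
  unrelated_cost_per_life_year: 0.0
  frontier_max_threshold: 150000
  frontier_step: 1000
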