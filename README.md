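# cvdcea

Generalized cost-effectiveness analysis of primary cardiovascular
disease (CVD) prevention: which mix of lifestyle, pharmaceutical and
population-wide interventions buys the most population health per
dollar?

The package is written for health economists and epidemiological
modellers.  It implements, as a tested and reusable Python library, the
full analytical machinery of a WHO-style generalized CEA of CVD primary
prevention in a national population aged 35–84:

- **Absolute-risk stratification.** A Framingham-style logistic
  equation predicts each person's 5-year probability of a first IHD or
  stroke event from age, sex, smoking, total and HDL cholesterol,
  diabetes and systolic blood pressure.  Rather than re-deriving cohort
  coefficients, predictions are scaled per age/sex cell so the mean
  calibrated risk matches observed first-event rates; the calibrated
  risk partitions the eligible (no prior CVD) population into the
  absolute-risk bands ≥15%, 10–14%, 5–9% and <5%.
- **Intervention effect algebra.** Drug effects enter as trial relative
  risks; risk-factor effects are converted at fixed rates (a 1% fall in
  systolic blood pressure gives a 3.4%/6.3% fall in IHD/stroke relative
  risk; a 1% fall in total cholesterol gives 1.8%/0.80%); sodium
  reductions map through an age-specific blood-pressure response.  All
  effects combine multiplicatively on the RR scale (statin × diuretic:
  0.70 × 0.86 = 0.602 for IHD), and population-level effects blend
  treated and untreated:
  `RR_eff = 1 − coverage · adherence(t) · (1 − RR)`,
  with 40% of initiators discontinuing after the first year.
- **A four-state discrete-time Markov cohort model** (well → IHD /
  stroke → dead, with GI bleeds as acute aspirin side-effect events),
  run in 5-year age/sex/risk-band cohorts until extinction, with
  secular trends on incidence and case fatality, DALY or QALY
  health-state weighting, disease treatment costs, and 3% annual
  discounting.
- **A back-calculated "do nothing" counterfactual**: observed rates are
  divided by the population-average effective RR of current practice,
  so re-applying current practice reproduces observed rates exactly —
  every strategy, including current practice, is evaluated against the
  same null.
- **Greedy expansion-path optimisation**: interventions join the
  package in order of incremental cost-effectiveness (cost-saving
  first), with exclusivity rules and a $50,000/DALY decision threshold;
  the path is the efficiency frontier.
- **Monte Carlo uncertainty analysis**: parameters are re-drawn per
  iteration (lognormal RRs, normal percent effects, gamma costs; shared
  parameters drawn once), yielding 95% uncertainty intervals, the
  probability of cost-effectiveness and the acceptability frontier.

All inputs are synthetic.  The generators produce an
order-of-magnitude-plausible Western population (~11 million aged
35–84), survey, rate tables, health-state weights and treatment costs
with the statistical structure the analysis assumes; they are **not**
calibrated to any real country (see `docs/methods.md`).

## Worked example

```python
import cvdcea as c

ctx = c.build_default_context(seed=1, n_per_cell=250)
salt = ctx.library["Mandatory salt reduction"]
scenario = c.Scenario(label="salt", entries=(c.ScenarioEntry(salt),))
outcome = c.evaluate_vs_null(ctx, scenario)
print(outcome.health_gain, outcome.net_cost, outcome.icer_display())
```

Running `python examples/04_single_intervention_cea.py` prints (among
others):

```
Mandatory salt reduction (everyone)
  health gain:                 121,765 DALYs
  program cost (gov):      175,876,087 AUD
  program cost (patient):            0 AUD
  treatment costs change: -753,600,018 AUD
  net cost:               -577,723,930 AUD
  cost-effectiveness:     Dominant
```

Mandating moderate salt limits in processed foods costs ~$0.81 per
person per year but averts enough IHD and stroke treatment to save
~$578M net over the cohort's lifetime while gaining ~122,000 discounted
DALYs — it is *Dominant* (cost-saving and health-improving) against the
do-nothing counterfactual.  The same run shows a thiazide diuretic for
the 5–9% risk band is also cost-saving, while the Australian-price
statin for the ≥15% band costs about $19,000 per DALY.

The other scripts in `examples/` walk through input generation, risk
calibration and stratification, the effect algebra, and the expansion
path with probabilistic uncertainty and the acceptability frontier —
each prints what it computes and what the numbers mean.

A thin CLI wraps the same machinery:

```bash
cvdcea generate --seed 1 --out-dir inputs      # synthetic input files
cvdcea frontier --builtin toy                  # expansion path
cvdcea report --builtin full                   # full scenario suite
```

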