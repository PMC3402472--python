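"""Generate the synthetic model inputs and look at their structure.

Builds the risk-factor survey (one row per respondent: age, sex,
smoking, cholesterol, blood pressure, diabetes, prior CVD) and the
age/sex epidemiology table (first-event incidence, case fatality,
background mortality, secular trends), and prints a few summaries.
"""

import cvdcea as c

demog = c.default_demography()
survey = c.generate_survey(demog, seed=1, n_per_cell=250)
epi = c.generate_epidemiology(seed=2)

print(f"population 35-84: {demog.total:,.0f} people in "
      f"{len(demog.cohort_sizes)} age/sex cohorts")
print(f"survey: {len(survey):,} respondents, "
      f"{survey['prior_cvd'].mean():.1%} with prior CVD (excluded from "
      "prevention eligibility)")
print(f"mean SBP {survey['sbp'].mean():.1f} mmHg, "
      f"mean total cholesterol {survey['total_chol'].mean():.2f} mmol/L, "
      f"smoking prevalence {survey['smoker'].mean():.1%}")

male = epi.frame.loc["male"]
print("\nmale IHD incidence per 1000 person-years by age band:")
print((male["ihd_incidence"] * 1000).round(2).to_string())
print("\n5-year first-event probability (male): "
      f"age 40: {epi.five_year_first_event_prob('male', 40):.4f}, "
      f"age 70: {epi.five_year_first_event_prob('male', 70):.4f}")
# Incidence rises steeply with age; the 5-year probabilities are what the
# risk equation is calibrated to reproduce.
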