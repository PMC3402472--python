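"""Predict, calibrate and stratify absolute cardiovascular risk.

The logistic risk equation predicts each survey respondent's 5-year
probability of a first IHD or stroke event; per-cell scale factors
calibrate the mean prediction to the observed event rates; the
calibrated risk then partitions the eligible population into the
absolute-risk bands >=15%, 10-14%, 5-9% and <5%.
"""

import cvdcea as c

demog = c.default_demography()
survey = c.generate_survey(demog, seed=1, n_per_cell=250)
epi = c.generate_epidemiology(seed=2)
eq = c.default_risk_equation()

cal = c.calibrate(survey, eq, epi)
print("calibration scale factors (male):")
print(cal.scales.loc["male"].round(3).to_string())

strata = c.stratify(survey, eq, cal)
counts = strata.frame.groupby(level="band")["eligible_count"].sum()
total = counts.sum()
print("\neligible survey population by risk band:")
for band in ("<5%", "5-9%", "10-14%", ">=15%"):
    print(f"  {band:>7}: {counts[band]:6.0f}  ({counts[band]/total:.1%})")

cell = strata.frame.loc[("male", 70)]
print("\nmale age 70-74 cell (mean_relative_risk is the band mean risk "
      "over the cell mean):")
print(cell.round(3).to_string())
# A scale below 1 means the raw equation over-predicts in that cell; the
# mean calibrated risk in every cell equals the observed 5-year
# first-event probability exactly.
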