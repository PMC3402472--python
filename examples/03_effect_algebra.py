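"""Intervention effect algebra: conversions and multiplicative combination.

Risk-factor effects (percent SBP or cholesterol reduction, absolute
sodium reduction) are converted to disease relative risks through fixed
conversion constants, then combined multiplicatively with direct drug
RRs.
"""

import cvdcea as c

# worked example: statin (RR IHD 0.70) plus thiazide diuretic (0.86)
rr_ihd, rr_stroke = c.combine_rrs([(0.70, 0.81), (0.86, 0.62)])
print(f"statin x diuretic: RR IHD = 0.70 x 0.86 = {rr_ihd:.3f}, "
      f"RR stroke = {rr_stroke:.3f}")

# a 1% SBP reduction -> 3.4% / 6.3% RR reduction (IHD / stroke)
print("1%% SBP reduction -> RR (IHD, stroke) = (%.3f, %.3f)"
      % c.rr_from_sbp_pct(1.0))
# phytosterol margarine: 7.5% total-cholesterol reduction
print("7.5%% TC reduction -> RR (IHD, stroke) = (%.3f, %.3f)"
      % c.rr_from_tc_pct(7.5))

# mandatory salt limits: sodium falls 10.6 mmol/day (men); the BP
# response strengthens with age
m = c.SodiumBPModel()
for age in (40, 60, 80):
    pct = c.sbp_pct_from_sodium(10.6, age, "male", m, baseline_sbp=130.0)
    rr = c.rr_from_sbp_pct(pct)
    print(f"  male age {age}: SBP -{pct:.2f}% -> RR IHD {rr[0]:.4f}, "
          f"RR stroke {rr[1]:.4f}")

# population blending: with 51% coverage and 40% year-1 discontinuation,
# the year-2 effective RR of a drug with RR 0.70 is
eff = c.population_effective_rr(0.70, 0.51, c.AdherenceModel(), sim_year=2)
print(f"population-effective RR in year 2 (drug RR 0.70, coverage 51%): "
      f"{eff:.4f}")
# Effects shrink toward 1 as coverage and adherence fall; harms (RR > 1)
# shrink the same way.
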