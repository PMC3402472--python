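# Methods

This note documents the model, its assumptions, the synthetic data
generators, the numerical choices and the known limitations of the
`cvdcea` package.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The decision problem

The package evaluates strategies for primary prevention of
cardiovascular disease — population-wide programs (limits on salt in
processed foods, a community heart health program) and primary-care
interventions (blood-pressure-lowering drug classes, statins, aspirin,
phytosterol margarine, dietary advice, an intensive lifestyle program)
offered by absolute-risk band — in a population aged 35–84 with no
prior CVD event.  Following the generalized-CEA framework, every
strategy, *including current practice*, is compared against a
counterfactual in which none of the interventions under study exist.
This makes current practice itself evaluable and lets the optimal mix
be assembled from scratch rather than incrementally to an inefficient
status quo.

## Risk prediction and calibration

Five-year first-event risk is predicted by a logistic equation in age,
sex, smoking status, total and HDL cholesterol, diabetes status and
systolic blood pressure.  The coefficients shipped as defaults are
documented placeholders with conventional signs and plausible
magnitudes, not estimates from any cohort.  This is deliberate: the
analysis never uses raw predictions.  Per age/sex cell, a scale factor
`s` is chosen so that the mean of `min(1, s·p_i)` over the cell's
survey respondents equals the observed 5-year first-event probability,
solved in closed form when no prediction is capped at 1 and by
bisection (to 1e-12) when capping binds.  Calibrated risk is therefore
anchored to the observed rates regardless of the equation's precise
coefficients; the equation only determines the *spread* of risk within
a cell, which drives stratification.

The observed 5-year first-event probability is derived from annual
incidence `λ` (IHD plus stroke) net of background mortality `m` with
the exponential competing-risks form `p = λ/(λ+m)·(1−e^{−5(λ+m)})`.

Stratification partitions the eligible population into the bands ≥15%,
10–14%, 5–9% and <5% of 5-year risk.  Each (sex, age band, risk band)
cell carries its eligible count and its mean risk relative to the cell
mean; the count-weighted mean of the relative risks is 1 in every cell,
so summing band cohorts reproduces cell-level event counts exactly.
Band membership and the relative-risk multiplier are fixed at baseline
entry; risk bands are not re-assessed as cohorts age (a simplification;
the alternative would need within-person risk-factor trajectories).

Primary-care interventions reach the fraction
`gp_attendance × assessment_participation` of their target bands
(defaults 0.85 × 0.60 = 0.51); population-wide interventions reach
everyone by construction.

## Effect algebra

Direct drug effects are relative risks for IHD and stroke (aspirin
additionally carries subtype-specific stroke RRs and a GI-bleed RR; its
net stroke RR is the haemorrhagic-fraction-weighted mean of the subtype
RRs at the rate level).  Risk-factor-mediated effects are converted
linearly: RR reduction = conversion constant × percent risk-factor
reduction (3.4%/6.3% per 1% SBP for IHD/stroke; 1.8%/0.80% per 1% total
cholesterol), floored at RR 0.01; a compounding (power) variant is
available behind a configuration switch for sensitivity with large
changes.  Sodium effects first map to a blood-pressure change through
an age-increasing slope (mmHg per mmol/day; 0.020 at age 35 rising by
0.0012 per year of age), expressed as a percentage of the cell's mean
baseline SBP.  Sodium amounts are interpreted in mmol/day — the
physically sensible unit for reformulation-scale changes (≈244 mg/day
for the mandatory limit) — with a flag to reinterpret as mg/day.

All effects combine multiplicatively on the RR scale, and cohort-level
effective RRs blend treated and untreated:
`RR_eff(t) = Π_i [1 − cov_i · adh_i(t) · scale_i · (1 − RR_i)]`.
`adh_i(t)` is 1 in year 1 and 0.60 thereafter for primary-care
interventions (40% discontinue within 12 months; discontinuers incur no
drug costs and no effect from year 2, while year-1 costs are charged to
all initiators); population-wide programs are sustained by ongoing
delivery.  `scale_i` is an efficacy-to-effectiveness discount: the
fraction of the trial effect realised in sustained routine delivery.
It defaults to 1 for drugs and structural interventions.  For the
counselling-based behaviour-change interventions (dietary advice, the
lifestyle program, the community heart health program) the shipped
analysis configuration sets it to 0.01, encoding the well-documented
collapse of counselling-induced risk-factor changes outside trial
conditions; costs are *not* scaled, since delivery costs the same
whether or not the effect persists.  This single parameter is what
makes the behaviour-change arms high-cost/small-effect; it is a
scenario configuration, not a library value — the catalogue stores
trial effects verbatim.

## The Markov cohort model

Four states: well, post-IHD, post-stroke, dead (absorbing); cycle
length one year; cohorts enter at the midpoint of their 5-year age band
in the reference year 2008 and are simulated until alive occupancy
falls below 1e-9 of the cohort or a configurable age cap (default 110,
at which point the remaining sliver is censored).  Within a cycle,
competing first events (IHD, stroke, GI bleed, background death) share
the combined exit probability `1 − e^{−ΣH}` in proportion to their
hazards — exact under constant within-cycle hazards and testable
against path enumeration.  Case fatality splits events into fatal and
non-fatal; non-fatal GI bleeds return to the well state (acute event:
one-cycle cost and disability decrement plus a per-event case
fatality).  Disease states are absorbing-while-alive (first-ever-event
cohorts; recurrent events are not separately counted) and carry an
additive excess mortality (defaults 0.02/year IHD, 0.045/year stroke)
on top of background mortality.  Incidence and case fatality drift by
annual trend multipliers (defaults 0.985 IHD, 0.99 stroke) raised to
the years since reference.

Occupancy is recorded at the start of each cycle and person-years at
risk are start-of-cycle alive occupancy; there is no half-cycle
correction by default (a plain discrete-time model), with a half-cycle
option behind configuration.  Health-adjusted life years weight
occupancy by the multiplicative complement of background and state
disability (DALY metric) or by utilities (QALY metric); with the
default matched weights (utility = 1 − disability at both levels) the
two metrics coincide exactly.  Disease costs charge incident events the
first-year cost and prevalent survivors the subsequent-year cost.  All
streams are discounted at `(1+r)^{−t}` with `t = 0` in the reference
year; the default rate is 3% (0% and 5% are standard sensitivity
settings).  An optional per-life-year unrelated health-care cost
implements the "other costs in added years of life" sensitivity
scenario (off by default).

## The do-nothing counterfactual

Per age/sex cell and event channel, the population-average steady-state
effective RR of current practice is the event-share-weighted mean over
risk bands (shares proportional to count × relative risk) of the
multiplicative band RRs at year-2 adherence.  Null incidence = observed
incidence / this average; `apply_practice` is the exact algebraic
inverse, so the round trip reproduces observed rates to machine
precision (the acceptance analysis reports ~1e-17).  Cohorts that age
past the oldest entry band carry their entry-band coverage forward, so
the adjustment spans the whole simulated age range.  All scenarios are
then simulated on the null rates, current practice included.

## Expansion path and uncertainty

The efficiency frontier is built greedily.  At each step every
remaining (intervention, band) candidate is evaluated *incrementally*:
the full model is re-simulated for package ∪ {candidate} and totals are
differenced — no analytic approximation of interactions — so
overlapping target populations and multiplicative residual-risk
shrinkage are captured exactly, which is why a candidate's incremental
gain never exceeds its standalone gain.  Cost-saving candidates join
first (largest health gain first); otherwise the lowest incremental
ICER wins, with ties broken lexicographically on (ICER, name, band) so
candidate order cannot change the path.  Exclusivity is configuration:
by default beta-blockers are skipped once any of the other three
blood-pressure drug classes is selected, and dietary advice and the
lifestyle program exclude each other.  The path is cut where the
incremental ICER first exceeds the decision threshold (default $50,000
per DALY).

Probabilistic sensitivity analysis re-draws intervention parameters per
iteration — RRs lognormal (moment-matched to mean and SE), percent
effects normal, costs gamma — with each named intervention drawn once
per iteration so parameters shared across scenarios (e.g. the statin RR
in current practice and in candidate packages) stay common, and common
random numbers across packages.  ICER uncertainty intervals order draws
from most to least cost-effective (cost-saving draws first, then rising
ratio, then draws with no health gain) and report the ratio at the
2.5th, 50th and 97.5th ranks; decision quantities (probability
cost-effective, acceptability frontier) are computed on the net
monetary benefit scale `λ·ΔE − ΔC`, which is stable where ratios are
not.  The acceptability frontier reports, per threshold on a 0–150,000
grid, the probability each package maximises NMB (ties to the earlier
label; probabilities sum to 1) and flags the package that is optimal on
mean NMB.

Deterministic tables report mean-based ICERs; PSA tables report medians
with 95% uncertainty intervals.

## Synthetic data: what it emulates and what it does not

The generators stand in for a national risk-factor survey, hospital and
mortality registers, and cost and disability sources, none of which are
publicly deposited for the original analysis.  They emulate: a 2008-like
population pyramid (~11.3M aged 35–84); risk factors normal within
age/sex strata with linear age drifts and realistic prevalences;
incidence and background mortality log-linear in age (IHD ~0.7 to ~22
per 1000 person-years across 35–84 in men); case fatality linear in
age; downward secular trends; plausible 2008-AUD treatment costs
(first-year/subsequent: IHD $9,500/$2,100, stroke $16,000/$4,400, GI
bleed $4,500 acute); and disability weights rising with age in the
background and fixed per state (IHD 0.14, stroke 0.30, GI bleed 0.10
acute).  Current practice is encoded as voluntary salt limits plus
partial band-targeted coverage of blood-pressure therapy (45/30/15%),
lipid therapy (30/20/10%) and dietary advice (10%).

They do **not** emulate: real between-factor correlations (factors are
independent within strata apart from the age drifts; a correlation
structure would sharpen stratification), real Australian rates or
prices, within-person risk-factor trajectories, or non-CVD benefits of
lifestyle change.  Consequently, passing tests demonstrate the
*machinery* — calibration, conservation, self-consistency, ordering and
uncertainty propagation — and the qualitative economics (a ~$1/person
structural intervention with population-wide reach is cost-saving; a
~$200/person/year counselling intervention with weak persistence costs
over $1M per DALY), not any country's absolute numbers.  Population
totals (e.g. the package's lifetime DALY gain) scale with the synthetic
demography and should be read as internally consistent magnitudes only.

The stroke haemorrhagic fraction defaults to 0.20 and baseline GI-bleed
incidence to ~0.8 per 1000 person-years at 60; both are configurable
placeholders where the evidence base is not public.

## Numerical choices

- Calibration bisection: 200 iterations or interval below 1e-12.
- Transition rows are validated to sum to 1 within 1e-12; assembled
  probabilities outside [0,1] raise a model error naming the cell.
- Extinction tolerance 1e-9 of cohort size; conservation of occupancy
  holds to 1e-9 by construction and is asserted in trace validation.
- Markov totals agree with exhaustive 3-cycle path enumeration to
  1e-12 and with the constant-hazard annuity closed form to 1e-9
  (both recomputed in the acceptance script).
- Degenerate inputs: zero cohorts, zero rates, empty streams and empty
  scenarios all return exact zeros rather than NaNs; draws with no
  health gain are handled on the NMB scale.
- Seeds: every stochastic component takes an explicit seed or
  `numpy.random.Generator`; identical seeds give bit-identical outputs
  (the scenario-suite runner writes no timestamps so whole result
  bundles are byte-reproducible).

## Problem sizes

Default analyses use 250 survey respondents per age/sex cell (5,000
total), 80 simulation units (2 sexes × 10 entry bands × 4 risk bands),
~70 annual cycles, and 200 Monte Carlo draws; the full expansion path
over the 29-candidate default set re-simulates the model a few hundred
times.  These sizes keep a complete analysis in the tens of seconds on
one CPU while leaving Monte Carlo error well below the structural
signals the package is designed to expose; all are parameters, not
constants.

## Known limitations

- Cohort (not individual) simulation: within-band heterogeneity enters
  only through the band mean relative risk.
- No secondary-prevention pathway beyond disease-state costs,
  disability and excess mortality; recurrent events are not counted.
- Eligibility and treatment effects are fixed at baseline entry; there
  is no re-screening as cohorts age.
- PSA draws are independent across parameters (no correlation matrix);
  epidemiological rates and health-state weights are treated as fixed
  in the PSA, which understates total uncertainty.
- The greedy path is not a budget-constrained optimisation; it is the
  standard league-table construction and can in principle differ from
  a knapsack optimum under strong interactions.
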