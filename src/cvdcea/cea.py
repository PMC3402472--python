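"""Generalized cost-effectiveness analysis.

All strategies — including current practice — are evaluated against a
theoretical "do nothing" comparator in which none of the interventions
under study exist.  Disease rates under "do nothing" are back-calculated
from currently observed rates by dividing out the population-average
effective relative risk of current practice, so that re-applying current
practice reproduces the observed rates.

The optimal strategy mix is built greedily: at every step each remaining
candidate (intervention, risk band) is evaluated incrementally to the
current package — effects combine multiplicatively and overlapping target
populations shrink each candidate's residual benefit — and the candidate
with the lowest incremental cost-effectiveness ratio joins the package
(cost-saving candidates first, ordered by health gain).  Probabilistic
sensitivity analysis propagates parameter uncertainty by Monte Carlo and
summarises the probability that each package is optimal as a function of
the willingness-to-pay threshold (the acceptability frontier).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, ModelError
from .interventions import (
    ConversionConstants,
    Intervention,
    RISK_BAND_LABELS,
    SodiumBPModel,
    annual_cost,
    sample_draw,
)
from .library import library_by_name, statin_nz_variant
from .markov import DiscountSpec, MarkovConfig, simulate_units
from .risk import (
    CalibrationFactors,
    RiskBandSpec,
    RiskEquation,
    RiskStrata,
    calibrate,
    coverage as pc_coverage_product,
    default_risk_equation,
    stratify,
)
from .synthetic import (
    AGE_BAND_STARTS,
    BAND_WIDTH,
    DemographySpec,
    DiseaseCostTable,
    EpidemiologyTable,
    HealthStateWeights,
    RateSpec,
    RiskFactorSpec,
    SEXES,
    default_demography,
    default_health_state_weights,
    generate_epidemiology,
    generate_survey,
    mean_sbp_table,
)

DEFAULT_THRESHOLD = 50_000.0   # AUD per DALY
FRONTIER_GRID = np.arange(0.0, 150_001.0, 1000.0)

#: An intervention is skipped from the expansion path once any of the
#: listed alternatives has been selected ("a more cost-effective
#: alternative is available").  Beta-blockers are a fourth-line
#: alternative to the other blood-pressure drug classes; dietary advice
#: and the intensive lifestyle program are alternatives to each other.
DEFAULT_EXCLUSIVITY: Mapping[str, frozenset[str]] = {
    "Beta-blocker": frozenset({"Thiazide diuretic", "Calcium channel blocker",
                               "ACE inhibitor"}),
    "Lifestyle program": frozenset({"Dietary advice"}),
    "Dietary advice": frozenset({"Lifestyle program"}),
}


# ---------------------------------------------------------------------------
# Scenario definition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioEntry:
    """One intervention in a scenario, with the risk bands it targets and
    an optional coverage override (float, or mapping band -> float).
    Without an override, primary-care entries use the context's
    GP-pathway coverage and population-wide entries cover everyone."""

    intervention: Intervention
    bands: tuple[str, ...] | None = None
    coverage: float | Mapping[str, float] | None = None

    @property
    def name(self) -> str:
        return self.intervention.name

    def target_bands(self) -> tuple[str, ...]:
        if self.intervention.delivery == "population_wide":
            return RISK_BAND_LABELS
        return self.bands if self.bands is not None \
            else self.intervention.target_bands


@dataclass(frozen=True)
class Scenario:
    """A named set of (intervention, band) components plus analysis
    settings; the do-nothing scenario is the empty entry tuple."""

    label: str
    entries: tuple[ScenarioEntry, ...] = ()
    metric: str = "DALY"

    def validate(self) -> None:
        seen = set()
        for e in self.entries:
            for b in e.target_bands():
                key = (e.name, b)
                if key in seen:
                    raise ConfigurationError(
                        f"scenario {self.label!r}: duplicate "
                        f"intervention/band pair {key}")
                seen.add(key)
        if self.metric not in ("DALY", "QALY"):
            raise ConfigurationError(
                f"scenario {self.label!r}: unknown metric {self.metric!r}")

    def with_entry(self, entry: ScenarioEntry, label=None) -> "Scenario":
        return replace(self, label=label or self.label,
                       entries=(*self.entries, entry))


DO_NOTHING = Scenario(label="do nothing")


# ---------------------------------------------------------------------------
# Model context
# ---------------------------------------------------------------------------

@dataclass
class ModelContext:
    """Everything a scenario evaluation needs, assembled once.

    Holds the synthetic population and survey, the observed and
    back-calculated epidemiology, calibrated risk strata, the simulation
    units (one cohort per sex x entry age band x risk band), and the
    shared economic settings.
    """

    demography: DemographySpec
    survey: pd.DataFrame
    epi_observed: EpidemiologyTable
    weights: HealthStateWeights
    cost_table: DiseaseCostTable
    risk_equation: RiskEquation
    calibration: CalibrationFactors
    bands: RiskBandSpec
    strata: RiskStrata
    units: pd.DataFrame
    baseline_sbp: pd.Series
    conv: ConversionConstants
    sodium_model: SodiumBPModel
    pc_coverage: float
    current_practice: Scenario
    discount: DiscountSpec
    markov: MarkovConfig
    library: dict[str, Intervention]
    threshold: float = DEFAULT_THRESHOLD
    epi_null: EpidemiologyTable | None = None
    _cache: dict = field(default_factory=dict, repr=False)

    # -- unit helpers -------------------------------------------------
    def unit_cells(self):
        """(sex_label, age_band, band_label) per unit row."""
        return list(zip(self.units["sex"], self.units["age_band"],
                        self.units["band"]))

    def null_totals(self, metric: str = "DALY") -> dict[str, float]:
        key = ("null", self.discount.rate, self.markov)
        if key not in self._cache:
            self._cache[key] = evaluate_scenario(self, DO_NOTHING)
        return self._cache[key]


def _build_units(demog: DemographySpec, strata: RiskStrata) -> pd.DataFrame:
    rows = []
    for sex in SEXES:
        for b in AGE_BAND_STARTS:
            pop = demog.size(sex, b)
            eligible_pop = pop * (1.0 - float(
                strata.prior_cvd_share.loc[(sex, b)]))
            cell = strata.frame.loc[(sex, b)]
            n_cell = cell["eligible_count"].sum()
            for band_label, row in cell.iterrows():
                share = (row["eligible_count"] / n_cell) if n_cell else 0.0
                rows.append({
                    "sex": sex, "age_band": b, "band": band_label,
                    "entry_age": b + BAND_WIDTH / 2,
                    "size": eligible_pop * share,
                    "rel_risk": row["mean_relative_risk"],
                })
    return pd.DataFrame(rows)


def default_current_practice(library: Mapping[str, Intervention]) -> Scenario:
    """Synthetic current-practice mix: voluntary salt limits, partial
    coverage of blood-pressure- and cholesterol-lowering therapy
    concentrated in the higher risk bands, and some dietary advice."""
    dietary = replace(library["Dietary advice"], effectiveness_scale=0.01)
    return Scenario(label="current practice", entries=(
        ScenarioEntry(library["Voluntary salt reduction"]),
        ScenarioEntry(library["BP-lowering (current practice)"],
                      coverage={">=15%": 0.45, "10-14%": 0.30, "5-9%": 0.15}),
        ScenarioEntry(library["Lipid-lowering (current practice)"],
                      coverage={">=15%": 0.30, "10-14%": 0.20, "5-9%": 0.10}),
        ScenarioEntry(dietary,
                      coverage={">=15%": 0.10, "10-14%": 0.10, "5-9%": 0.10}),
    ))


def build_default_context(
    seed: int = 0,
    *,
    demography: DemographySpec | None = None,
    rate_spec: RateSpec | None = None,
    rf_spec: RiskFactorSpec | None = None,
    n_per_cell: int = 250,
    gp_attendance: float = 0.85,
    assessment_participation: float = 0.60,
    discount: DiscountSpec | None = None,
    markov: MarkovConfig | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    current_practice: Scenario | None = None,
    weights: HealthStateWeights | None = None,
    cost_table: DiseaseCostTable | None = None,
) -> ModelContext:
    """Generate inputs, calibrate, stratify and back-calculate the null.

    Deterministic given ``seed``.  This is the one-stop entry point used
    by the examples, the scenario-suite runner and the acceptance
    analyses.
    """
    demog = demography or default_demography()
    rf = rf_spec or RiskFactorSpec()
    survey = generate_survey(demog, rf, seed=seed, n_per_cell=n_per_cell)
    epi = generate_epidemiology(rate_spec, seed=seed + 1)
    eq = default_risk_equation()
    cal = calibrate(survey, eq, epi)
    bands = RiskBandSpec()
    strata = stratify(survey, eq, cal, bands)
    units = _build_units(demog, strata)
    lib = library_by_name()
    ctx = ModelContext(
        demography=demog,
        survey=survey,
        epi_observed=epi,
        weights=weights or default_health_state_weights(),
        cost_table=cost_table or DiseaseCostTable(),
        risk_equation=eq,
        calibration=cal,
        bands=bands,
        strata=strata,
        units=units,
        baseline_sbp=mean_sbp_table(rf),
        conv=ConversionConstants(),
        sodium_model=SodiumBPModel(),
        pc_coverage=pc_coverage_product(
            strata, gp_attendance, assessment_participation),
        current_practice=current_practice
        or default_current_practice(lib),
        discount=discount or DiscountSpec(),
        markov=markov or MarkovConfig(),
        library=lib,
        threshold=threshold,
    )
    ctx.epi_null = backcalculate_null(ctx)
    return ctx


# ---------------------------------------------------------------------------
# Effective relative risks per unit
# ---------------------------------------------------------------------------

def _entry_coverage(ctx: ModelContext, entry: ScenarioEntry) -> np.ndarray:
    """Covered fraction of each unit for one scenario entry."""
    targeted = entry.target_bands()
    cov_spec = entry.coverage
    cache_key = ("cov", entry.intervention.delivery, targeted,
                 tuple(sorted(cov_spec.items()))
                 if isinstance(cov_spec, Mapping) else cov_spec)
    cached = ctx._cache.get(cache_key)
    if cached is not None:
        return cached
    n = len(ctx.units)
    cov = np.zeros(n)
    default = (1.0 if entry.intervention.delivery == "population_wide"
               else ctx.pc_coverage)
    for i, band in enumerate(ctx.units["band"]):
        if band not in targeted:
            continue
        c = entry.coverage
        if c is None:
            cov[i] = default
        elif isinstance(c, Mapping):
            cov[i] = float(c.get(band, 0.0))
        else:
            cov[i] = float(c)
    if ((cov < 0) | (cov > 1)).any():
        raise ConfigurationError(
            f"entry {entry.name!r}: coverage outside [0, 1]")
    ctx._cache[cache_key] = cov
    return cov


def _effect_key(effect) -> tuple:
    sod = (tuple(sorted(effect.sodium_by_sex.items()))
           if effect.sodium_by_sex else None)
    return (effect.rr_ihd, effect.rr_stroke, effect.rr_stroke_isch,
            effect.rr_stroke_haem, effect.rr_gi_bleed, effect.sbp_pct,
            effect.tc_pct, sod)


def _entry_rr(ctx: ModelContext, iv: Intervention) -> np.ndarray:
    """Resolved (rr_ihd, rr_stroke, rr_gi) per unit for one intervention,
    evaluated at each unit's entry age/sex cell.  Cached per effect
    specification (the resolution depends only on the effect and the
    fixed context tables)."""
    key = ("rr", _effect_key(iv.effect))
    cached = ctx._cache.get(key)
    if cached is not None:
        return cached
    cells = ctx._cache.get("unit_cells_static")
    if cells is None:
        cells = []
        for row in ctx.units.itertuples(index=False):
            cell = ctx.epi_observed.frame.loc[(row.sex, row.age_band)]
            cells.append((
                row.sex, float(row.entry_age),
                float(cell["stroke_haemorrhagic_fraction"]),
                float(ctx.baseline_sbp.loc[(row.sex, row.age_band)])))
        ctx._cache["unit_cells_static"] = cells
    n = len(ctx.units)
    out = np.ones((n, 3))
    for i, (sex, entry_age, hf, sbp) in enumerate(cells):
        out[i] = iv.effect.resolve(
            sex, entry_age, haem_fraction=hf, conv=ctx.conv,
            sodium_model=ctx.sodium_model, baseline_sbp=sbp,
        )
    if len(ctx._cache) > 8192:   # PSA draws produce unique effects
        ctx._cache.clear()
    ctx._cache[key] = out
    return out


def _scenario_terms(
    ctx: ModelContext, scenario: Scenario,
    draws: Mapping[str, Intervention] | None = None,
):
    """Per-entry (intervention, coverage vector, resolved RR matrix)."""
    terms = []
    for entry in scenario.entries:
        iv = entry.intervention
        if draws is not None and iv.name in draws:
            # graft the drawn parameters onto the scenario's intervention,
            # preserving scenario-specific settings (price variant costs,
            # effect maintenance)
            drawn = draws[iv.name]
            has_cost_unc = any(p in iv.uncertainty
                               for p in ("cost_year1", "cost_subsequent"))
            iv = replace(iv, effect=drawn.effect,
                         costs=drawn.costs if has_cost_unc else iv.costs)
        cov = _entry_coverage(ctx, entry)
        rr = _entry_rr(ctx, iv)
        terms.append((iv, cov, rr))
    return terms


def _rr_fn(terms):
    def rr_fn(sim_year: int) -> np.ndarray:
        eff = None
        for iv, cov, rr in terms:
            sf = iv.sustained_fraction(sim_year)
            f = 1.0 - cov[:, None] * sf * (1.0 - rr)
            eff = f if eff is None else eff * f
        if eff is None:
            return np.ones((1, 3))
        return eff
    return rr_fn


def _int_cost_fn(ctx: ModelContext, terms):
    size = ctx.units["size"].to_numpy(float)

    def cost_fn(sim_year: int, alive_frac: np.ndarray):
        gov = np.zeros(len(size))
        pat = np.zeros(len(size))
        for iv, cov, _rr in terms:
            g = annual_cost(iv, sim_year, 1.0, perspective="government")
            p = annual_cost(iv, sim_year, 1.0, perspective="patient")
            base = size * cov * alive_frac
            gov += base * g
            pat += base * p
        return gov, pat
    return cost_fn


def evaluate_scenario(
    ctx: ModelContext,
    scenario: Scenario,
    draws: Mapping[str, Intervention] | None = None,
    return_trace: bool = False,
):
    """Simulate every cohort unit under a scenario on the do-nothing
    baseline rates, returning discounted population totals."""
    scenario.validate()
    epi = ctx.epi_null if ctx.epi_null is not None else ctx.epi_observed
    terms = _scenario_terms(ctx, scenario, draws)
    trace = simulate_units(
        ctx.units, epi, ctx.weights, ctx.cost_table,
        rr_fn=_rr_fn(terms) if terms else None,
        int_cost_fn=_int_cost_fn(ctx, terms) if terms else None,
        config=ctx.markov)
    totals = trace.totals(ctx.discount)
    if return_trace:
        return totals, trace
    return totals


# ---------------------------------------------------------------------------
# Back-calculated "do nothing" rates
# ---------------------------------------------------------------------------

def population_average_rr(
    ctx: ModelContext, scenario: Scenario | None = None,
) -> pd.DataFrame:
    """Population-average steady-state effective RR of a scenario per
    (sex, age band) and channel (ihd, stroke, gi_bleed).

    Band strata are weighted by their share of cell events (count times
    mean relative risk); within a band the entries' population-effective
    RRs at steady-state adherence multiply.
    """
    scenario = scenario or ctx.current_practice
    terms = _scenario_terms(ctx, scenario)
    n = len(ctx.units)
    rr_units = np.ones((n, 3))
    for iv, cov, rr in terms:
        sf = iv.sustained_fraction(2)   # steady state
        rr_units *= 1.0 - cov[:, None] * sf * (1.0 - rr)
    units = ctx.units
    weight = (units["size"] * units["rel_risk"]).to_numpy(float)
    rows = {}
    for sex in SEXES:
        for b in AGE_BAND_STARTS:
            mask = ((units["sex"] == sex)
                    & (units["age_band"] == b)).to_numpy()
            w = weight[mask]
            if w.sum() <= 0:
                rows[(sex, b)] = np.ones(3)
                continue
            rows[(sex, b)] = (rr_units[mask] * w[:, None]).sum(0) / w.sum()
    # cohorts aged past the oldest entry band stay covered at their
    # entry-band rate; carry the oldest entry band's average forward so
    # back-calculation is consistent over the whole simulated age range
    oldest = AGE_BAND_STARTS[-1]
    for sex in SEXES:
        for b in sorted({bb for _, bb in ctx.epi_observed.frame.index}):
            if (sex, b) not in rows:
                rows[(sex, b)] = rows[(sex, oldest)]
    frame = pd.DataFrame(
        {k: v for k, v in zip(("ihd", "stroke", "gi_bleed"),
                              np.array(list(rows.values())).T)},
        index=pd.MultiIndex.from_tuples(rows.keys(),
                                        names=["sex", "age_band"]))
    if (frame <= 0).any().any():
        raise ModelError("population-average effective RR <= 0")
    return frame


_CHANNEL_COLS = {"ihd": "ihd_incidence", "stroke": "stroke_incidence",
                 "gi_bleed": "gi_bleed_incidence"}


def backcalculate_null(
    ctx: ModelContext,
    observed: EpidemiologyTable | None = None,
    current_practice: Scenario | None = None,
) -> EpidemiologyTable:
    """Disease rates in the counterfactual where none of the interventions
    exist: observed incidence divided by the population-average effective
    RR of current practice (per cell and channel).  Re-applying current
    practice with :func:`apply_practice` recovers the observed rates."""
    observed = observed or ctx.epi_observed
    avg = population_average_rr(ctx, current_practice)
    frame = observed.frame.copy()
    for channel, col in _CHANNEL_COLS.items():
        scale = avg[channel].reindex(frame.index).fillna(1.0)
        frame[col] = frame[col] / scale
    null = EpidemiologyTable(frame)
    null.validate()
    return null


def apply_practice(
    null: EpidemiologyTable, avg_rr: pd.DataFrame,
) -> EpidemiologyTable:
    """Scale do-nothing incidence by a population-average effective RR
    table (the exact inverse of :func:`backcalculate_null`)."""
    frame = null.frame.copy()
    for channel, col in _CHANNEL_COLS.items():
        scale = avg_rr[channel].reindex(frame.index).fillna(1.0)
        frame[col] = frame[col] * scale
    return EpidemiologyTable(frame)


# ---------------------------------------------------------------------------
# Outcomes
# ---------------------------------------------------------------------------

@dataclass
class CEAOutcome:
    """Discounted lifetime outcome of a scenario against its comparator.

    ``treatment_cost_change`` is scenario minus comparator disease
    treatment cost (negative when treatment costs are averted);
    ``net_cost = cost_gov + cost_patient + treatment_cost_change``.
    ``classification`` is "dominant" (cost-saving with health gain),
    "dominated" (costlier with no gain), "saving_with_harm", or "icer".
    """

    label: str
    metric: str
    health_gain: float
    cost_gov: float
    cost_patient: float
    treatment_cost_change: float

    @property
    def net_cost(self) -> float:
        return self.cost_gov + self.cost_patient + self.treatment_cost_change

    @property
    def classification(self) -> str:
        if self.health_gain > 0:
            return "dominant" if self.net_cost < 0 else "icer"
        if self.net_cost >= 0:
            return "dominated"
        return "saving_with_harm"

    @property
    def is_dominant(self) -> bool:
        return self.classification == "dominant"

    @property
    def icer(self) -> float | None:
        """Net cost per unit health gain; None where the ratio is not
        informative (dominant or dominated)."""
        if self.classification == "icer":
            return self.net_cost / self.health_gain
        return None

    def icer_display(self) -> str:
        c = self.classification
        if c == "dominant":
            return "Dominant"
        if c == "dominated":
            return "Dominated"
        if c == "saving_with_harm":
            return "Cost-saving, health loss"
        return f"{self.icer:,.0f}"


def outcome_from_totals(
    label: str, metric: str,
    totals: Mapping[str, float], comparator: Mapping[str, float],
) -> CEAOutcome:
    haly = "haly_daly" if metric == "DALY" else "haly_qaly"
    return CEAOutcome(
        label=label, metric=metric,
        health_gain=totals[haly] - comparator[haly],
        cost_gov=totals["cost_gov"] - comparator["cost_gov"],
        cost_patient=totals["cost_patient"] - comparator["cost_patient"],
        treatment_cost_change=(totals["disease_cost"]
                               - comparator["disease_cost"]),
    )


def evaluate_vs_null(
    ctx: ModelContext,
    scenario: Scenario,
    draws: Mapping[str, Intervention] | None = None,
    null_totals: Mapping[str, float] | None = None,
) -> CEAOutcome:
    """Evaluate one scenario against the do-nothing comparator."""
    null_totals = null_totals or ctx.null_totals()
    totals = evaluate_scenario(ctx, scenario, draws)
    return outcome_from_totals(scenario.label, scenario.metric, totals,
                               null_totals)


# ---------------------------------------------------------------------------
# Expansion path
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Candidate:
    intervention: Intervention
    band: str | None = None     # None for population-wide (all bands)

    @property
    def key(self) -> tuple[str, str]:
        return (self.intervention.name, self.band or "all")

    def entry(self) -> ScenarioEntry:
        bands = (None if self.band is None else (self.band,))
        return ScenarioEntry(self.intervention, bands=bands)


@dataclass
class ExpansionStep:
    name: str
    band: str
    inc_gain: float
    inc_net: float
    inc_icer: float | None       # None when the step is cost-saving
    dominant: bool
    cum_gain: float
    cum_net: float


@dataclass
class ExpansionPath:
    """Greedy efficiency frontier: the ordered steps, the final package,
    candidates skipped with their reasons, and the index of the first
    step whose incremental ICER exceeds the decision threshold (None if
    every step is under it)."""

    steps: list[ExpansionStep]
    package: Scenario
    skipped: list[tuple[str, str, str]]
    threshold: float

    @property
    def threshold_cut(self) -> int | None:
        for i, s in enumerate(self.steps):
            if not s.dominant and s.inc_icer is not None \
                    and s.inc_icer > self.threshold:
                return i
        return None

    def package_under_threshold(self) -> list[ExpansionStep]:
        cut = self.threshold_cut
        return self.steps if cut is None else self.steps[:cut]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.steps):
            rows.append({
                "step": i + 1, "intervention": s.name, "band": s.band,
                "inc_health_gain": s.inc_gain, "inc_net_cost": s.inc_net,
                "inc_icer": "Dominant" if s.dominant else
                (f"{s.inc_icer:.0f}" if s.inc_icer is not None
                 else "Dominated"),
                "cum_health_gain": s.cum_gain, "cum_net_cost": s.cum_net,
            })
        return pd.DataFrame(rows)


def default_candidates(
    ctx: ModelContext, statin_price: str = "australia",
    behaviour_effectiveness_scale: float = 0.01,
) -> list[Candidate]:
    """The candidate set: both population-wide programs, and each
    primary-care intervention in each targetable risk band.

    ``behaviour_effectiveness_scale`` is the efficacy-to-effectiveness
    discount applied to the counselling-based behaviour-change
    interventions (dietary advice, the lifestyle program and the
    community heart health program), whose trial effects translate only
    fractionally into sustained routine delivery.
    """
    lib = ctx.library
    statin = lib["Statin"]
    if statin_price == "nz":
        statin = statin_nz_variant(statin)
    elif statin_price != "australia":
        raise ConfigurationError(
            f"unknown statin price scenario {statin_price!r}")
    behavioural = {"Dietary advice", "Lifestyle program",
                   "Community heart health program"}
    primary_care = ["Thiazide diuretic", "Beta-blocker",
                    "Calcium channel blocker", "ACE inhibitor", "Aspirin",
                    "Statin", "Phytosterol margarine", "Dietary advice",
                    "Lifestyle program"]
    chhp = replace(lib["Community heart health program"],
                   effectiveness_scale=behaviour_effectiveness_scale)
    out = [Candidate(lib["Mandatory salt reduction"]), Candidate(chhp)]
    for name in primary_care:
        iv = statin if name == "Statin" else lib[name]
        if name in behavioural:
            iv = replace(iv,
                         effectiveness_scale=behaviour_effectiveness_scale)
        for band in (">=15%", "10-14%", "5-9%"):
            out.append(Candidate(iv, band))
    return out


def expansion_path(
    ctx: ModelContext,
    candidates: Sequence[Candidate] | None = None,
    exclusivity: Mapping[str, frozenset[str]] | None = None,
    threshold: float | None = None,
    metric: str = "DALY",
) -> ExpansionPath:
    """Build the efficiency frontier by greedy incremental ICER.

    At each step every remaining candidate is re-evaluated incrementally
    to the current package (full re-simulation of package plus
    candidate); cost-saving candidates are added first (largest health
    gain first), then the candidate with the lowest incremental ICER.
    Candidates whose exclusivity alternative is already in the package
    are skipped; candidates with no residual health gain are skipped as
    dominated.  Ties break on (ICER, name, band), so reordering the
    candidate list cannot change the path.
    """
    if candidates is None:
        candidates = default_candidates(ctx)
    if not candidates:
        raise ConfigurationError("expansion path: empty candidate list")
    excl = DEFAULT_EXCLUSIVITY if exclusivity is None else exclusivity
    threshold = ctx.threshold if threshold is None else threshold
    haly = "haly_daly" if metric == "DALY" else "haly_qaly"

    null = ctx.null_totals()

    def net_of(totals):
        return (totals["cost_gov"] - null["cost_gov"]
                + totals["cost_patient"] - null["cost_patient"]
                + totals["disease_cost"] - null["disease_cost"])

    package = Scenario(label="package", metric=metric)
    pkg_totals = null
    selected_names: set[str] = set()
    remaining = list(candidates)
    steps: list[ExpansionStep] = []
    skipped: list[tuple[str, str, str]] = []
    cum_gain = 0.0
    cum_net = 0.0

    while remaining:
        # drop exclusivity-blocked candidates first
        still = []
        for c in remaining:
            blockers = excl.get(c.intervention.name, frozenset())
            if blockers & selected_names:
                skipped.append((c.intervention.name, c.band or "all",
                                "more cost-effective alternative available"))
            else:
                still.append(c)
        remaining = still
        if not remaining:
            break

        evals = []
        for c in remaining:
            trial = package.with_entry(c.entry())
            totals = evaluate_scenario(ctx, trial)
            gain = totals[haly] - pkg_totals[haly]
            net = net_of(totals) - cum_net
            evals.append((c, trial, totals, gain, net))

        dominant = [e for e in evals if e[3] > 0 and e[4] < 0]
        if dominant:
            best = max(dominant, key=lambda e: (e[3], e[0].key))
        else:
            with_gain = [e for e in evals if e[3] > 0]
            if not with_gain:
                for c, *_ in evals:
                    skipped.append((c.intervention.name, c.band or "all",
                                    "no incremental health gain"))
                break
            best = min(with_gain,
                       key=lambda e: (e[4] / e[3], e[0].key))
        c, trial, totals, gain, net = best
        cum_gain += gain
        cum_net += net
        steps.append(ExpansionStep(
            name=c.intervention.name, band=c.band or "all",
            inc_gain=gain, inc_net=net,
            inc_icer=None if net < 0 else net / gain,
            dominant=net < 0, cum_gain=cum_gain, cum_net=cum_net))
        package = trial
        pkg_totals = totals
        selected_names.add(c.intervention.name)
        remaining = [r for r in remaining if r.key != c.key]

    return ExpansionPath(steps=steps, package=package, skipped=skipped,
                         threshold=threshold)


def package_scenario(
    ctx: ModelContext, path: ExpansionPath, label: str = "optimal package",
) -> Scenario:
    """Scenario containing the path's steps up to the decision
    threshold."""
    keep = {(s.name, s.band) for s in path.package_under_threshold()}
    entries = tuple(
        e for e in path.package.entries
        if (e.name, (e.bands[0] if e.bands else "all")) in keep
        or (e.name, "all") in keep)
    return Scenario(label=label, entries=entries,
                    metric=path.package.metric)


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

def psa_engine(
    sample_fn: Callable[[np.random.Generator], object],
    evaluate_fn: Callable[[object], Mapping[str, float]],
    n_draws: int,
    seed: int,
) -> pd.DataFrame:
    """Generic Monte Carlo propagation: draw parameters, evaluate, stack.

    Returns one row per draw.  Fully reproducible given ``seed``; with a
    degenerate sampler every row is identical.
    """
    if n_draws < 2:
        raise ConfigurationError(f"n_draws must be >= 2, got {n_draws}")
    rng = np.random.default_rng(seed)
    rows = [dict(evaluate_fn(sample_fn(rng))) for _ in range(n_draws)]
    return pd.DataFrame(rows)


def summarize_draws(values: np.ndarray) -> dict[str, float]:
    v = np.asarray(values, float)
    return {
        "mean": float(v.mean()),
        "median": float(np.quantile(v, 0.5)),
        "lo95": float(np.quantile(v, 0.025)),
        "hi95": float(np.quantile(v, 0.975)),
    }


def icer_quantiles(
    gain: np.ndarray, net: np.ndarray,
    qs: Sequence[float] = (0.025, 0.5, 0.975),
) -> list[object]:
    """Draw-wise cost-effectiveness ratio quantiles.

    Draws are ordered from most to least cost-effective: cost-saving
    draws with health gain ("Dominant") first, then increasing ICER,
    then draws with no health gain last.  Each requested quantile is the
    ratio of the draw at that rank — reported as the string "Dominant"
    where that draw is cost-saving.
    """
    gain = np.asarray(gain, float)
    net = np.asarray(net, float)
    key = np.where((gain > 0) & (net < 0), -np.inf,
                   np.where(gain > 0, net / np.where(gain > 0, gain, 1.0),
                            np.inf))
    order = np.argsort(key, kind="stable")
    out = []
    n = len(order)
    for q in qs:
        i = order[min(n - 1, int(round(q * (n - 1))))]
        if gain[i] > 0 and net[i] < 0:
            out.append("Dominant")
        elif gain[i] <= 0:
            out.append("Dominated")
        else:
            out.append(float(net[i] / gain[i]))
    return out


@dataclass
class PSAResult:
    """Per-scenario Monte Carlo draws and their summaries."""

    draws: dict[str, pd.DataFrame]    # label -> columns gain, gov, pat, treat
    seed: int
    threshold: float

    def gain_net(self, label: str) -> tuple[np.ndarray, np.ndarray]:
        d = self.draws[label]
        net = (d["cost_gov"] + d["cost_patient"]
               + d["treatment_cost_change"]).to_numpy()
        return d["health_gain"].to_numpy(), net

    def summary(self, label: str) -> dict[str, object]:
        d = self.draws[label]
        gain, net = self.gain_net(label)
        lo, med, hi = icer_quantiles(gain, net)
        nmb = self.threshold * gain - net
        return {
            "label": label,
            "health_gain": summarize_draws(gain),
            "net_cost": summarize_draws(net),
            "cost_gov": summarize_draws(d["cost_gov"].to_numpy()),
            "cost_patient": summarize_draws(d["cost_patient"].to_numpy()),
            "treatment_cost_change": summarize_draws(
                d["treatment_cost_change"].to_numpy()),
            "icer_lo95": lo, "icer_median": med, "icer_hi95": hi,
            "prob_cost_effective": float((nmb > 0).mean()),
        }


def run_psa(
    ctx: ModelContext,
    scenarios: Mapping[str, Scenario],
    n_draws: int,
    seed: int,
    threshold: float | None = None,
) -> PSAResult:
    """Monte Carlo uncertainty analysis over intervention parameters.

    Per iteration, every library intervention is re-drawn once (so a
    parameter shared between scenarios is sampled once) and each scenario
    is re-evaluated against the deterministic do-nothing baseline using
    common random numbers across scenarios.
    """
    if n_draws < 2:
        raise ConfigurationError(f"n_draws must be >= 2, got {n_draws}")
    threshold = ctx.threshold if threshold is None else threshold
    rng = np.random.default_rng(seed)
    null = ctx.null_totals()
    names_needed = {e.name for sc in scenarios.values()
                    for e in sc.entries}
    base = [iv for name, iv in ctx.library.items() if name in names_needed]
    records: dict[str, list[dict]] = {label: [] for label in scenarios}
    for _ in range(n_draws):
        drawn = {iv.name: sample_draw(iv, rng) for iv in base}
        for label, sc in scenarios.items():
            outcome = evaluate_vs_null(ctx, sc, draws=drawn,
                                       null_totals=null)
            records[label].append({
                "health_gain": outcome.health_gain,
                "cost_gov": outcome.cost_gov,
                "cost_patient": outcome.cost_patient,
                "treatment_cost_change": outcome.treatment_cost_change,
            })
    draws = {label: pd.DataFrame(rows) for label, rows in records.items()}
    return PSAResult(draws=draws, seed=seed, threshold=threshold)


# ---------------------------------------------------------------------------
# Acceptability frontier
# ---------------------------------------------------------------------------

def acceptability_frontier(
    package_draws: Mapping[str, tuple[np.ndarray, np.ndarray]],
    thresholds: Sequence[float] = FRONTIER_GRID,
) -> pd.DataFrame:
    """Probability each package is optimal per willingness-to-pay value.

    ``package_draws`` maps package label to aligned (health gain, net
    cost) draw arrays sharing common random numbers.  Per threshold and
    draw the optimal package maximises net monetary benefit
    (threshold x gain - net cost; ties go to the earlier label, a
    documented deterministic rule).  Returns a frame indexed by threshold
    with one probability column per package (rows sum to 1) and columns
    ``optimal_package`` / ``frontier_probability`` for the package that
    is optimal on mean NMB at that threshold.
    """
    labels = list(package_draws)
    if not labels:
        raise DataError("acceptability_frontier: no packages")
    lengths = {len(np.asarray(package_draws[k][0])) for k in labels} | \
        {len(np.asarray(package_draws[k][1])) for k in labels}
    if len(lengths) != 1:
        raise DataError(
            "acceptability_frontier: misaligned draw counts across "
            f"packages ({sorted(lengths)})")
    gains = np.column_stack([np.asarray(package_draws[k][0], float)
                             for k in labels])
    nets = np.column_stack([np.asarray(package_draws[k][1], float)
                            for k in labels])
    if gains.shape[0] < 1 or gains.shape != nets.shape:
        raise DataError("acceptability_frontier: misaligned draw arrays")
    rows = []
    for lam in thresholds:
        nmb = lam * gains - nets
        winner = nmb.argmax(axis=1)
        probs = np.bincount(winner, minlength=len(labels)) / gains.shape[0]
        det = int(np.argmax(lam * gains.mean(0) - nets.mean(0)))
        row = {"threshold": float(lam),
               **{k: probs[j] for j, k in enumerate(labels)},
               "optimal_package": labels[det],
               "frontier_probability": probs[det]}
        rows.append(row)
    return pd.DataFrame(rows).set_index("threshold")


# ---------------------------------------------------------------------------
# Package ledger (lifetime costs and health gain summary)
# ---------------------------------------------------------------------------

def package_ledger(
    ctx: ModelContext,
    scenario: Scenario,
    psa: PSAResult | None = None,
) -> pd.DataFrame:
    """Lifetime health gain and cost components of a package vs the
    do-nothing comparator.

    Rows: health gain, intervention cost to government, intervention cost
    to patients, disease treatment costs averted (negative when averted)
    and net lifetime cost (the exact sum of the three cost components,
    per draw when PSA draws are supplied)."""
    outcome = evaluate_vs_null(ctx, scenario)
    rows = {
        "health_gain": outcome.health_gain,
        "intervention_cost_government": outcome.cost_gov,
        "intervention_cost_patients": outcome.cost_patient,
        "treatment_costs_averted": outcome.treatment_cost_change,
        "net_lifetime_cost": outcome.net_cost,
    }
    frame = pd.DataFrame({"value": rows})
    if psa is not None and scenario.label in psa.draws:
        d = psa.draws[scenario.label]
        net = (d["cost_gov"] + d["cost_patient"]
               + d["treatment_cost_change"]).to_numpy()
        uis = {
            "health_gain": summarize_draws(d["health_gain"].to_numpy()),
            "intervention_cost_government":
                summarize_draws(d["cost_gov"].to_numpy()),
            "intervention_cost_patients":
                summarize_draws(d["cost_patient"].to_numpy()),
            "treatment_costs_averted":
                summarize_draws(d["treatment_cost_change"].to_numpy()),
            "net_lifetime_cost": summarize_draws(net),
        }
        frame["lo95"] = [uis[k]["lo95"] for k in rows]
        frame["hi95"] = [uis[k]["hi95"] for k in rows]
    return frame
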