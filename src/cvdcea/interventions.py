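"""Interventions: effect algebra, cost schedules, adherence and sampling.

An intervention either acts directly on disease relative risks (drugs with
trial-measured RRs for IHD and stroke) or acts through a risk factor
(percent reduction in systolic blood pressure or total cholesterol, or an
absolute reduction in daily sodium intake).  Risk-factor effects are first
converted to relative risks using fixed conversion constants from
meta-analyses of blood-pressure- and cholesterol-lowering trials; all
effects then combine multiplicatively on the RR scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, DomainError

RISK_BAND_LABELS = ("<5%", "5-9%", "10-14%", ">=15%")
TARGETABLE_BANDS = ("5-9%", "10-14%", ">=15%")


# ---------------------------------------------------------------------------
# Conversion of risk-factor changes to relative risks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConversionConstants:
    """Percent RR reduction per 1% risk-factor reduction.

    A 1% reduction in systolic blood pressure gives a 3.4% reduction in
    IHD relative risk and 6.3% in stroke relative risk; a 1% reduction in
    total cholesterol gives 1.8% (IHD) and 0.80% (stroke).
    """

    sbp_to_ihd: float = 3.4
    sbp_to_stroke: float = 6.3
    tc_to_ihd: float = 1.8
    tc_to_stroke: float = 0.80
    rr_floor: float = 0.01
    mode: str = "linear"   # "linear" or "power" (compounding) scaling

    def validate(self) -> None:
        for f in ("sbp_to_ihd", "sbp_to_stroke", "tc_to_ihd", "tc_to_stroke"):
            v = getattr(self, f)
            if not 0 < v < 100:
                raise ConfigurationError(f"{f}: must be in (0, 100), got {v}")
        if self.mode not in ("linear", "power"):
            raise ConfigurationError(f"mode: unknown scaling {self.mode!r}")


def _rr_pair(delta_pct: float, k_ihd: float, k_stroke: float,
             floor: float, mode: str) -> tuple[float, float]:
    if not -100 < delta_pct < 100:
        raise DomainError(
            f"risk-factor percent change must be in (-100, 100), "
            f"got {delta_pct}")
    if mode == "power":
        rr_i = (1.0 - k_ihd / 100.0) ** delta_pct
        rr_s = (1.0 - k_stroke / 100.0) ** delta_pct
    else:
        rr_i = 1.0 - k_ihd / 100.0 * delta_pct
        rr_s = 1.0 - k_stroke / 100.0 * delta_pct
    return max(rr_i, floor), max(rr_s, floor)


def rr_from_sbp_pct(
    delta_pct: float, k: ConversionConstants | None = None,
) -> tuple[float, float]:
    """(RR_ihd, RR_stroke) for a ``delta_pct`` percent reduction in
    systolic blood pressure.  Negative ``delta_pct`` (a rise) yields
    RR > 1."""
    k = k or ConversionConstants()
    return _rr_pair(delta_pct, k.sbp_to_ihd, k.sbp_to_stroke,
                    k.rr_floor, k.mode)


def rr_from_tc_pct(
    delta_pct: float, k: ConversionConstants | None = None,
) -> tuple[float, float]:
    """(RR_ihd, RR_stroke) for a ``delta_pct`` percent reduction in total
    cholesterol."""
    k = k or ConversionConstants()
    return _rr_pair(delta_pct, k.tc_to_ihd, k.tc_to_stroke,
                    k.rr_floor, k.mode)


# ---------------------------------------------------------------------------
# Sodium -> blood pressure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SodiumBPModel:
    """Systolic blood pressure response to a change in daily sodium intake.

    ``slope(age, sex)`` is the mmHg fall in SBP per unit (mmol/day by
    default) fall in sodium; the response strengthens with age, as in the
    trial-derived sodium/blood-pressure relationships.  Encoded as a
    linear function of age for simplicity; a per-cell table can override.

    ``units`` records the interpretation of sodium amounts ("mmol" or
    "mg"); with "mg" the slope is rescaled by 1/23 (mg per mmol of Na).
    """

    slope_at_35: float = 0.020
    slope_age_gradient: float = 0.0012   # per year of age
    units: str = "mmol"
    table: Mapping[tuple[str, int], float] | None = None

    def slope(self, age: float, sex: str) -> float:
        if self.table is not None:
            key = (sex, int(age) - int(age) % 5)
            if key not in self.table:
                raise ConfigurationError(
                    f"sodium-BP model: missing cell {key}")
            s = float(self.table[key])
        else:
            s = self.slope_at_35 + self.slope_age_gradient * (age - 35.0)
        s = max(s, 0.0)
        if self.units == "mg":
            s /= 23.0
        return s


def sbp_pct_from_sodium(
    delta_na: float, age: float, sex: str,
    m: SodiumBPModel | None = None, baseline_sbp: float = 130.0,
) -> float:
    """Percent SBP reduction from a ``delta_na`` per-day sodium reduction.

    ``percent = 100 * slope(age, sex) * delta_na / baseline_sbp``.
    """
    if baseline_sbp <= 0:
        raise DomainError(f"baseline_sbp must be > 0, got {baseline_sbp}")
    m = m or SodiumBPModel()
    return 100.0 * m.slope(age, sex) * delta_na / baseline_sbp


# ---------------------------------------------------------------------------
# Combining effects
# ---------------------------------------------------------------------------

def combine_rrs(
    effects: Iterable[tuple[float, float]],
) -> tuple[float, float]:
    """Componentwise product of (RR_ihd, RR_stroke) pairs.

    Combination is multiplicative and therefore order-independent; effects
    mediated by risk factors must already be converted to RRs before
    entering.
    """
    effects = list(effects)
    if not effects:
        raise DomainError("combine_rrs: empty effect list")
    rr_i, rr_s = 1.0, 1.0
    for e_i, e_s in effects:
        if e_i <= 0 or e_s <= 0:
            raise DomainError(f"combine_rrs: non-positive RR ({e_i}, {e_s})")
        rr_i *= e_i
        rr_s *= e_s
    return rr_i, rr_s


# ---------------------------------------------------------------------------
# Adherence, costs, uncertainty
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AdherenceModel:
    """Discontinuation model: 40% of initiators are no longer adherent
    after 12 months; retention thereafter defaults to complete."""

    year1_discontinuation: float = 0.40
    post_year1_retention: float = 1.0

    def validate(self) -> None:
        for f in ("year1_discontinuation", "post_year1_retention"):
            v = getattr(self, f)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{f}: must be in [0, 1], got {v}")

    def adherent_fraction(self, sim_year: int) -> float:
        """Fraction of initiators still on treatment in simulation year
        ``sim_year`` (1-based)."""
        if sim_year <= 1:
            return 1.0
        return ((1.0 - self.year1_discontinuation)
                * self.post_year1_retention ** (sim_year - 2))


#: Adherence for interventions sustained by ongoing delivery
#: (population-wide programs): nobody discontinues.
FULL_ADHERENCE = AdherenceModel(year1_discontinuation=0.0)


@dataclass(frozen=True)
class CostSchedule:
    """Annual per-person cost (2008 AUD), split government/patient.

    ``year1`` covers intervention initiation (e.g. GP visits, baseline
    blood tests); ``subsequent`` is the ongoing annual cost for those who
    remain adherent.
    """

    year1_gov: float
    year1_patient: float = 0.0
    subsequent_gov: float | None = None
    subsequent_patient: float | None = None

    def __post_init__(self):
        if self.subsequent_gov is None:
            object.__setattr__(self, "subsequent_gov", self.year1_gov)
        if self.subsequent_patient is None:
            object.__setattr__(self, "subsequent_patient", self.year1_patient)
        for f in ("year1_gov", "year1_patient",
                  "subsequent_gov", "subsequent_patient"):
            if getattr(self, f) < 0:
                raise ConfigurationError(f"cost schedule: {f} must be >= 0")

    @property
    def year1_total(self) -> float:
        return self.year1_gov + self.year1_patient

    @property
    def subsequent_total(self) -> float:
        return self.subsequent_gov + self.subsequent_patient

    def split(self, sim_year: int, perspective: str) -> float:
        gov = self.year1_gov if sim_year <= 1 else self.subsequent_gov
        pat = self.year1_patient if sim_year <= 1 else self.subsequent_patient
        if perspective == "government":
            return gov
        if perspective == "patient":
            return pat
        if perspective == "both":
            return gov + pat
        raise DomainError(f"unknown cost perspective {perspective!r}")


@dataclass(frozen=True)
class ParamUncertainty:
    """Uncertainty specification for one parameter: mean, standard error
    and a distribution family ("lognormal", "normal" or "gamma")."""

    mean: float
    se: float
    family: str = "normal"

    def validate(self, name: str) -> None:
        if self.se < 0:
            raise ConfigurationError(f"uncertainty[{name}]: SE must be >= 0")
        if self.family not in ("lognormal", "normal", "gamma"):
            raise ConfigurationError(
                f"uncertainty[{name}]: unknown family {self.family!r}")

    def draw(self, rng: np.random.Generator) -> float:
        if self.se == 0:
            return self.mean
        if self.family == "lognormal":
            # moment-matched: E[X] = mean, SD[X] = se
            sigma2 = math.log1p((self.se / self.mean) ** 2)
            mu = math.log(self.mean) - sigma2 / 2.0
            return float(rng.lognormal(mu, math.sqrt(sigma2)))
        if self.family == "gamma":
            shape = (self.mean / self.se) ** 2
            scale = self.se ** 2 / self.mean
            return float(rng.gamma(shape, scale))
        return float(rng.normal(self.mean, self.se))


# ---------------------------------------------------------------------------
# Effect specification and the Intervention record
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectSpec:
    """What an intervention does, in the measure its evidence uses.

    Any subset of channels may be present; they combine multiplicatively
    after conversion to relative risks.  ``rr_stroke_isch``/``rr_stroke_haem``
    give subtype-specific stroke effects (aspirin); the net stroke RR is
    the haemorrhagic-fraction-weighted mean of the subtype RRs at the rate
    level.  ``sodium_by_sex`` is an absolute daily sodium reduction
    (units per :class:`SodiumBPModel`).
    """

    rr_ihd: float | None = None
    rr_stroke: float | None = None
    rr_stroke_isch: float | None = None
    rr_stroke_haem: float | None = None
    rr_gi_bleed: float | None = None
    sbp_pct: float | None = None
    tc_pct: float | None = None
    sodium_by_sex: Mapping[str, float] | None = None

    def validate(self) -> None:
        for f in ("rr_ihd", "rr_stroke", "rr_stroke_isch", "rr_stroke_haem",
                  "rr_gi_bleed"):
            v = getattr(self, f)
            if v is not None and v <= 0:
                raise ConfigurationError(f"effect.{f}: RR must be > 0")
        for f in ("sbp_pct", "tc_pct"):
            v = getattr(self, f)
            if v is not None and not -100 < v < 100:
                raise ConfigurationError(
                    f"effect.{f}: must be in (-100, 100)")

    def resolve(
        self,
        sex: str,
        age: float,
        *,
        haem_fraction: float = 0.2,
        conv: ConversionConstants | None = None,
        sodium_model: SodiumBPModel | None = None,
        baseline_sbp: float = 130.0,
    ) -> tuple[float, float, float]:
        """Resolve to ``(rr_ihd, rr_stroke, rr_gi_bleed)`` for one
        age/sex cell."""
        conv = conv or ConversionConstants()
        rr_i, rr_s, rr_g = 1.0, 1.0, 1.0
        if self.rr_ihd is not None:
            rr_i *= self.rr_ihd
        if self.rr_stroke is not None:
            rr_s *= self.rr_stroke
        if self.rr_stroke_isch is not None or self.rr_stroke_haem is not None:
            isch = self.rr_stroke_isch if self.rr_stroke_isch is not None \
                else 1.0
            haem = self.rr_stroke_haem if self.rr_stroke_haem is not None \
                else 1.0
            rr_s *= (1.0 - haem_fraction) * isch + haem_fraction * haem
        if self.rr_gi_bleed is not None:
            rr_g *= self.rr_gi_bleed
        if self.sbp_pct is not None:
            a, b = rr_from_sbp_pct(self.sbp_pct, conv)
            rr_i *= a
            rr_s *= b
        if self.tc_pct is not None:
            a, b = rr_from_tc_pct(self.tc_pct, conv)
            rr_i *= a
            rr_s *= b
        if self.sodium_by_sex is not None:
            delta = float(self.sodium_by_sex[sex])
            pct = sbp_pct_from_sodium(delta, age, sex, sodium_model,
                                      baseline_sbp)
            a, b = rr_from_sbp_pct(pct, conv)
            rr_i *= a
            rr_s *= b
        return rr_i, rr_s, rr_g


@dataclass(frozen=True)
class Intervention:
    """One preventive intervention: delivery mode, targeted risk bands,
    effect, cost schedule, adherence and parameter uncertainty.

    ``effectiveness_scale`` is the fraction of the trial efficacy realised
    in sustained routine delivery (an efficacy-to-effectiveness discount;
    1.0 = the trial effect carries over fully).  Costs are not scaled by
    it: delivering an intervention costs the same whether or not its
    effect persists.
    """

    name: str
    delivery: str                    # "population_wide" | "primary_care"
    effect: EffectSpec
    costs: CostSchedule
    target_bands: tuple[str, ...] = TARGETABLE_BANDS
    adherence: AdherenceModel = field(default_factory=AdherenceModel)
    uncertainty: Mapping[str, ParamUncertainty] = field(default_factory=dict)
    effectiveness_scale: float = 1.0
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        if self.delivery not in ("population_wide", "primary_care"):
            raise ConfigurationError(
                f"{self.name}: unknown delivery {self.delivery!r}")
        if self.delivery == "population_wide":
            object.__setattr__(self, "target_bands", RISK_BAND_LABELS)
        self.effect.validate()
        self.adherence.validate()
        for pname, u in self.uncertainty.items():
            u.validate(f"{self.name}.{pname}")
        if not 0 <= self.effectiveness_scale <= 1:
            raise ConfigurationError(
                f"{self.name}: effectiveness_scale must be in [0, 1]")

    def sustained_fraction(self, sim_year: int) -> float:
        """Fraction of the trial effect operating in ``sim_year`` among
        covered initiators: adherent fraction times the
        efficacy-to-effectiveness scale."""
        af = (1.0 if self.delivery == "population_wide"
              else self.adherence.adherent_fraction(sim_year))
        return af * self.effectiveness_scale


# ---------------------------------------------------------------------------
# Population-level blending
# ---------------------------------------------------------------------------

def population_effective_rr(
    rr, coverage: float, adherence: AdherenceModel, sim_year: int,
):
    """Blend treated and untreated: effective RR
    ``1 - coverage * adherent_fraction(sim_year) * (1 - rr)``.

    Accepts a scalar RR, an RR tuple, or an ndarray (applied
    elementwise).  Works for harms (rr > 1) symmetrically.
    """
    if not 0 <= coverage <= 1:
        raise ConfigurationError(f"coverage must be in [0, 1], got {coverage}")
    af = adherence.adherent_fraction(sim_year)
    if isinstance(rr, tuple):
        return tuple(1.0 - coverage * af * (1.0 - r) for r in rr)
    return 1.0 - coverage * af * (1.0 - np.asarray(rr)) \
        if isinstance(rr, np.ndarray) else 1.0 - coverage * af * (1.0 - rr)


def annual_cost(
    iv: Intervention, sim_year: int, coverage: float,
    adherence: AdherenceModel | None = None, perspective: str = "both",
) -> float:
    """Per-person annual intervention cost in the target population.

    Year 1 charges the initiation cost to all covered initiators; later
    years charge the ongoing cost only to those still adherent.
    """
    if not 0 <= coverage <= 1:
        raise ConfigurationError(f"coverage must be in [0, 1], got {coverage}")
    adh = adherence or iv.adherence
    per_person = iv.costs.split(sim_year, perspective)
    af = 1.0 if sim_year <= 1 else (
        1.0 if iv.delivery == "population_wide"
        else adh.adherent_fraction(sim_year))
    return coverage * af * per_person


# ---------------------------------------------------------------------------
# Probabilistic draws
# ---------------------------------------------------------------------------

_EFFECT_PARAMS = {"rr_ihd", "rr_stroke", "rr_stroke_isch", "rr_stroke_haem",
                  "rr_gi_bleed", "sbp_pct", "tc_pct",
                  "sodium_male", "sodium_female"}
_COST_PARAMS = {"cost_year1", "cost_subsequent"}


def sample_draw(iv: Intervention, rng: np.random.Generator) -> Intervention:
    """Resample an intervention's uncertain parameters.

    RRs are drawn lognormal (moment-matched to mean/SE), percent effects
    normal, costs gamma, as declared per parameter; draws are truncated to
    respect type invariants.  With all SEs zero the draw equals the mean.
    Deterministic given the rng state.
    """
    effect_updates: dict[str, object] = {}
    cost_updates: dict[str, float] = {}
    for pname, u in iv.uncertainty.items():
        if pname not in _EFFECT_PARAMS | _COST_PARAMS:
            raise ConfigurationError(
                f"{iv.name}: unknown uncertain parameter {pname!r}")
        val = u.draw(rng)
        if pname in ("sodium_male", "sodium_female"):
            sex = "male" if pname == "sodium_male" else "female"
            sod = dict(effect_updates.get("sodium_by_sex")
                       or iv.effect.sodium_by_sex or {})
            sod[sex] = val
            effect_updates["sodium_by_sex"] = sod
        elif pname in _EFFECT_PARAMS:
            if pname.startswith("rr_"):
                val = max(val, 1e-6)
            else:
                val = float(np.clip(val, -99.9, 99.9))
            effect_updates[pname] = val
        elif pname == "cost_year1":
            val = max(val, 0.0)
            scale = val / iv.costs.year1_total if iv.costs.year1_total else 0.0
            cost_updates["year1_gov"] = iv.costs.year1_gov * scale
            cost_updates["year1_patient"] = iv.costs.year1_patient * scale
        elif pname == "cost_subsequent":
            val = max(val, 0.0)
            base = iv.costs.subsequent_total
            scale = val / base if base else 0.0
            cost_updates["subsequent_gov"] = iv.costs.subsequent_gov * scale
            cost_updates["subsequent_patient"] = (
                iv.costs.subsequent_patient * scale)
    effect = replace(iv.effect, **effect_updates) if effect_updates \
        else iv.effect
    costs = replace(iv.costs, **cost_updates) if cost_updates else iv.costs
    return replace(iv, effect=effect, costs=costs)


def draw_library(
    interventions: Sequence[Intervention], rng: np.random.Generator,
) -> dict[str, Intervention]:
    """Draw every intervention once, keyed by name.

    A parameter shared between scenarios (e.g. the statin RR used both in
    current practice and in candidate packages) is therefore drawn exactly
    once per Monte Carlo iteration.
    """
    return {iv.name: sample_draw(iv, rng) for iv in interventions}
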