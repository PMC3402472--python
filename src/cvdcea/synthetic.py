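"""Synthetic epidemiology: population, survey and rate-table generators.

The analysis needs four kinds of input that, for the original Australian
study population, came from sources that are not publicly deposited: an
individual-level risk-factor survey, age/sex tables of first-event
incidence and case fatality, health-state weights, and disease treatment
costs.  This module generates all of them with the statistical structure
the downstream analysis assumes, so that every stage of the pipeline is
testable without any external data.

The generated numbers are order-of-magnitude plausible for a Western
population (e.g. IHD incidence rising from well under 1 to tens of events
per 1000 person-years between ages 35 and 85) but are deliberately not
calibrated to any real country's rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

SEXES: tuple[str, str] = ("male", "female")

#: 5-year age-band lower bounds for cohort entry (spanning [35, 85)).
AGE_BAND_STARTS: tuple[int, ...] = tuple(range(35, 85, 5))

#: Age bands for epidemiology tables extend beyond entry ages because
#: cohorts are simulated until extinction (default age cap 110).
EPI_BAND_STARTS: tuple[int, ...] = tuple(range(35, 110, 5))

BAND_WIDTH = 5

SURVEY_COLUMNS = [
    "age", "sex", "smoker", "total_chol", "hdl_chol", "diabetes", "sbp",
    "prior_cvd",
]

EPI_COLUMNS = [
    "ihd_incidence", "stroke_incidence", "ihd_case_fatality",
    "stroke_case_fatality", "background_mortality", "ihd_trend",
    "stroke_trend", "stroke_haemorrhagic_fraction", "gi_bleed_incidence",
    "gi_bleed_case_fatality",
]


def age_band(age: float, starts: Sequence[int] = EPI_BAND_STARTS) -> int:
    """Lower bound of the 5-year band containing ``age`` (clipped to the
    covered range)."""
    lo, hi = starts[0], starts[-1]
    b = int(age) - int(age) % BAND_WIDTH
    return min(max(b, lo), hi)


# ---------------------------------------------------------------------------
# Individual records and demography
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndividualRecord:
    """One survey respondent's risk-factor profile.

    Units: age in years, cholesterol in mmol/L, systolic blood pressure
    in mmHg.
    """

    age: float
    sex: str
    smoker: bool
    total_chol: float
    hdl_chol: float
    diabetes: bool
    sbp: float
    prior_cvd: bool = False

    def validate(self) -> None:
        if not (35 <= self.age < 85):
            raise DataError(f"age {self.age} outside [35, 85)")
        if self.sex not in SEXES:
            raise DataError(f"unknown sex label {self.sex!r}")
        if not (self.total_chol > self.hdl_chol > 0):
            raise DataError(
                f"require total_chol > hdl_chol > 0, got "
                f"{self.total_chol} / {self.hdl_chol}")
        if not (70 < self.sbp < 260):
            raise DataError(f"sbp {self.sbp} outside (70, 260)")


@dataclass(frozen=True)
class DemographySpec:
    """Population structure: 5-year age/sex cohorts spanning ages 35-84.

    ``cohort_sizes`` maps ``(sex, band_start)`` to the number of people in
    that cohort in the reference year.
    """

    cohort_sizes: Mapping[tuple[str, int], float]
    age_band_starts: tuple[int, ...] = AGE_BAND_STARTS
    sex_labels: tuple[str, str] = SEXES
    reference_year: int = 2008

    def validate(self) -> None:
        starts = self.age_band_starts
        if tuple(sorted(starts)) != starts or len(set(starts)) != len(starts):
            raise ConfigurationError("age_band_starts: must be sorted, unique")
        expected = tuple(range(35, 85, BAND_WIDTH))
        if starts != expected:
            raise ConfigurationError(
                "age_band_starts: bands must be contiguous 5-year intervals "
                f"covering [35, 85), got {starts}")
        for sex in self.sex_labels:
            for b in starts:
                size = self.cohort_sizes.get((sex, b))
                if size is None:
                    raise ConfigurationError(
                        f"cohort_sizes: missing cell ({sex}, {b})")
                if not size > 0:
                    raise ConfigurationError(
                        f"cohort_sizes[({sex}, {b})]: must be > 0, got {size}")

    def size(self, sex: str, band: int) -> float:
        return float(self.cohort_sizes[(sex, band)])

    @property
    def total(self) -> float:
        return float(sum(self.cohort_sizes.values()))


def default_demography() -> DemographySpec:
    """A Western-style 2008 population pyramid for ages 35-84.

    Counts (thousands per sex per band) taper with age roughly like the
    Australian 2008 structure; absolute totals (~11 million aged 35-84)
    only set the scale of population-level results.
    """
    per_band = [790, 760, 745, 735, 680, 580, 460, 355, 270, 175]  # thousands
    sizes = {}
    for sex in SEXES:
        for b, n in zip(AGE_BAND_STARTS, per_band):
            adj = 1.0 if sex == "male" else 1.03  # female survival advantage
            sizes[(sex, b)] = n * 1000.0 * adj
    return DemographySpec(cohort_sizes=sizes)


# ---------------------------------------------------------------------------
# Risk-factor survey generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SexFactorSpec:
    """Risk-factor distribution parameters for one sex.

    Continuous factors are normal within an age/sex stratum with a linear
    age drift (per year of age relative to age 50); binary factors are
    Bernoulli with a linear age drift in prevalence.  This mirrors the
    broad age patterns of population risk-factor surveys while keeping
    every moment analytically known for testing.
    """

    sbp_mean: float = 127.0          # mmHg at age 50
    sbp_sd: float = 15.0
    sbp_age_slope: float = 0.45      # mmHg per year of age
    tc_mean: float = 5.5             # mmol/L at age 50
    tc_sd: float = 1.0
    tc_age_slope: float = 0.012
    hdl_mean: float = 1.35           # mmol/L
    hdl_sd: float = 0.32
    smoking_prev: float = 0.22       # at age 50
    smoking_age_slope: float = -0.004
    diabetes_prev: float = 0.06
    diabetes_age_slope: float = 0.003
    prior_cvd_prev: float = 0.04
    prior_cvd_age_slope: float = 0.004

    def validate(self, label: str) -> None:
        for f in ("sbp_sd", "tc_sd", "hdl_sd"):
            if not getattr(self, f) > 0:
                raise ConfigurationError(f"{label}.{f}: scale must be > 0")
        for f in ("smoking_prev", "diabetes_prev", "prior_cvd_prev"):
            v = getattr(self, f)
            if not 0 <= v <= 1:
                raise ConfigurationError(
                    f"{label}.{f}: probability must be in [0, 1], got {v}")


@dataclass(frozen=True)
class RiskFactorSpec:
    """Per-sex risk-factor distributions.

    Factors are drawn independently within age/sex strata apart from the
    linear age drifts; a joint correlation structure is not modelled (the
    original individual-level survey correlations are not available) but
    the independence assumption is a documented property of the generator,
    not of the method.
    """

    male: SexFactorSpec = field(default_factory=SexFactorSpec)
    female: SexFactorSpec = field(
        default_factory=lambda: SexFactorSpec(
            sbp_mean=124.0, tc_mean=5.4, hdl_mean=1.55,
            smoking_prev=0.18, diabetes_prev=0.05, prior_cvd_prev=0.025))

    def for_sex(self, sex: str) -> SexFactorSpec:
        return self.male if sex == "male" else self.female

    def validate(self) -> None:
        self.male.validate("male")
        self.female.validate("female")


def generate_survey(
    demog: DemographySpec,
    rf_spec: RiskFactorSpec | None = None,
    seed: int = 0,
    n_per_cell: int = 250,
) -> pd.DataFrame:
    """Generate a synthetic individual-level risk-factor survey.

    Returns a DataFrame with one row per respondent and the documented
    columns ``age, sex, smoker, total_chol, hdl_chol, diabetes, sbp,
    prior_cvd``.  Deterministic given ``seed``.  Ages are uniform within
    each 5-year band; continuous factors drift linearly with age.

    Respondents flagged ``prior_cvd`` remain in the survey (they inform
    the eligible-population share) but are excluded from all downstream
    risk prediction and eligibility.
    """
    demog.validate()
    spec = rf_spec or RiskFactorSpec()
    spec.validate()
    if n_per_cell <= 0:
        raise ConfigurationError(f"n_per_cell: must be > 0, got {n_per_cell}")
    rng = np.random.default_rng(seed)
    frames = []
    for sex in demog.sex_labels:
        s = spec.for_sex(sex)
        for b in demog.age_band_starts:
            n = n_per_cell
            age = rng.uniform(b, b + BAND_WIDTH, size=n)
            d_age = age - 50.0
            sbp = rng.normal(s.sbp_mean + s.sbp_age_slope * d_age, s.sbp_sd)
            sbp = np.clip(sbp, 75.0, 255.0)
            tc = rng.normal(s.tc_mean + s.tc_age_slope * d_age, s.tc_sd)
            tc = np.clip(tc, 2.5, 12.0)
            hdl = rng.normal(s.hdl_mean, s.hdl_sd)
            hdl = np.clip(hdl, 0.4, 0.9 * tc)
            smoker = rng.random(n) < np.clip(
                s.smoking_prev + s.smoking_age_slope * d_age, 0, 1)
            diabetes = rng.random(n) < np.clip(
                s.diabetes_prev + s.diabetes_age_slope * d_age, 0, 1)
            prior = rng.random(n) < np.clip(
                s.prior_cvd_prev + s.prior_cvd_age_slope * d_age, 0, 1)
            frames.append(pd.DataFrame({
                "age": age, "sex": sex, "smoker": smoker,
                "total_chol": tc, "hdl_chol": hdl, "diabetes": diabetes,
                "sbp": sbp, "prior_cvd": prior,
            }))
    survey = pd.concat(frames, ignore_index=True)
    return survey


def survey_to_records(survey: pd.DataFrame) -> list[IndividualRecord]:
    """Convert a survey frame to a list of validated records."""
    records = []
    for row in survey.itertuples(index=False):
        rec = IndividualRecord(
            age=float(row.age), sex=str(row.sex), smoker=bool(row.smoker),
            total_chol=float(row.total_chol), hdl_chol=float(row.hdl_chol),
            diabetes=bool(row.diabetes), sbp=float(row.sbp),
            prior_cvd=bool(row.prior_cvd))
        rec.validate()
        records.append(rec)
    return records


def write_survey(survey: pd.DataFrame, path) -> None:
    """Export a survey as CSV with the documented header."""
    survey[SURVEY_COLUMNS].to_csv(path, index=False)


def read_survey(path) -> pd.DataFrame:
    """Read a survey CSV; validates the documented header."""
    frame = pd.read_csv(path)
    missing = [c for c in SURVEY_COLUMNS if c not in frame.columns]
    if missing:
        raise DataError(f"survey file {path}: missing columns {missing}")
    return frame[SURVEY_COLUMNS]


def mean_sbp_table(
    rf_spec: RiskFactorSpec | None = None,
    band_starts: Sequence[int] = EPI_BAND_STARTS,
) -> pd.Series:
    """Expected baseline systolic blood pressure per (sex, age band).

    Used to express absolute blood-pressure changes (e.g. from sodium
    reduction) as percentage reductions.  Bands beyond the survey range
    extrapolate the linear drift.
    """
    spec = rf_spec or RiskFactorSpec()
    idx = pd.MultiIndex.from_product(
        [SEXES, list(band_starts)], names=["sex", "age_band"])
    vals = []
    for sex, b in idx:
        s = spec.for_sex(sex)
        mid = b + BAND_WIDTH / 2
        vals.append(s.sbp_mean + s.sbp_age_slope * (mid - 50.0))
    return pd.Series(vals, index=idx, name="sbp")


# ---------------------------------------------------------------------------
# Epidemiology tables
# ---------------------------------------------------------------------------

@dataclass
class EpidemiologyTable:
    """Age/sex table of event rates, case fatality and secular trends.

    Wraps a DataFrame indexed by ``(sex, age_band)`` with columns:
    ``ihd_incidence`` and ``stroke_incidence`` (first events per
    person-year), ``ihd_case_fatality`` / ``stroke_case_fatality``
    (probability an incident event is fatal), ``background_mortality``
    (non-CVD deaths per person-year), ``ihd_trend`` / ``stroke_trend``
    (annual multiplicative drift applied to incidence and case fatality),
    ``stroke_haemorrhagic_fraction``, ``gi_bleed_incidence`` and
    ``gi_bleed_case_fatality``.
    """

    frame: pd.DataFrame

    def validate(self) -> None:
        missing = [c for c in EPI_COLUMNS if c not in self.frame.columns]
        if missing:
            raise DataError(f"epidemiology table: missing columns {missing}")
        f = self.frame
        rate_cols = ["ihd_incidence", "stroke_incidence",
                     "background_mortality", "gi_bleed_incidence"]
        if (f[rate_cols] < 0).any().any():
            raise DataError("epidemiology table: negative rate")
        prob_cols = ["ihd_case_fatality", "stroke_case_fatality",
                     "stroke_haemorrhagic_fraction", "gi_bleed_case_fatality"]
        if ((f[prob_cols] < 0) | (f[prob_cols] > 1)).any().any():
            raise DataError(
                "epidemiology table: case fatality/fraction outside [0, 1]")
        for c in ("ihd_trend", "stroke_trend"):
            if ((f[c] <= 0.8) | (f[c] >= 1.2)).any():
                raise DataError(
                    f"epidemiology table: {c} outside (0.8, 1.2)")

    def cell(self, sex: str, age: float) -> pd.Series:
        return self.frame.loc[(sex, age_band(age))]

    def copy(self) -> "EpidemiologyTable":
        return EpidemiologyTable(self.frame.copy())

    def five_year_first_event_prob(self, sex: str, band: int) -> float:
        """Combined 5-year probability of a first IHD or stroke event.

        Uses the exponential competing-risks form with background
        mortality as the competing hazard:
        ``p = lam/(lam+m) * (1 - exp(-5*(lam+m)))``.
        """
        row = self.frame.loc[(sex, band)]
        lam = float(row.ihd_incidence + row.stroke_incidence)
        m = float(row.background_mortality)
        if lam == 0:
            return 0.0
        tot = lam + m
        return lam / tot * -float(np.expm1(-5.0 * tot))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "EpidemiologyTable":
        frame = pd.read_csv(path, index_col=[0, 1])
        table = cls(frame)
        table.validate()
        return table


@dataclass(frozen=True)
class SexRateSpec:
    """Exponential age-gradient rate curves for one sex.

    Incidence per person-year at the reference age 60 with a log-linear
    age gradient; case fatality linear in age (clipped to [0, 1]);
    background (non-CVD) mortality is Gompertz.
    """

    ihd_at_60: float = 4.0e-3
    ihd_log_slope: float = 0.075      # per year of age
    stroke_at_60: float = 1.6e-3
    stroke_log_slope: float = 0.090
    ihd_cf_at_60: float = 0.22
    ihd_cf_slope: float = 0.006
    stroke_cf_at_60: float = 0.25
    stroke_cf_slope: float = 0.007
    mort_at_60: float = 5.0e-3        # non-CVD deaths / person-year
    mort_log_slope: float = 0.092
    gi_bleed_at_60: float = 8.0e-4
    gi_log_slope: float = 0.05

    def validate(self, label: str) -> None:
        for f in ("ihd_at_60", "stroke_at_60", "mort_at_60", "gi_bleed_at_60"):
            if getattr(self, f) < 0:
                raise ConfigurationError(f"{label}.{f}: rate must be >= 0")
        for f in ("ihd_cf_at_60", "stroke_cf_at_60"):
            v = getattr(self, f)
            if not 0 <= v <= 1:
                raise ConfigurationError(
                    f"{label}.{f}: probability must be in [0, 1], got {v}")


@dataclass(frozen=True)
class RateSpec:
    """Per-sex rate curves plus trend and side-effect settings."""

    male: SexRateSpec = field(default_factory=SexRateSpec)
    female: SexRateSpec = field(default_factory=lambda: SexRateSpec(
        ihd_at_60=2.0e-3, stroke_at_60=1.3e-3, mort_at_60=3.2e-3))
    ihd_trend: float = 0.985          # annual multiplier on incidence & CF
    stroke_trend: float = 0.99
    stroke_haemorrhagic_fraction: float = 0.20
    gi_bleed_case_fatality: float = 0.03

    def for_sex(self, sex: str) -> SexRateSpec:
        return self.male if sex == "male" else self.female

    def validate(self) -> None:
        self.male.validate("male")
        self.female.validate("female")
        for f in ("ihd_trend", "stroke_trend"):
            v = getattr(self, f)
            if not 0.8 < v < 1.2:
                raise ConfigurationError(
                    f"{f}: trend multiplier must be in (0.8, 1.2), got {v}")
        if not 0 <= self.stroke_haemorrhagic_fraction <= 1:
            raise ConfigurationError(
                "stroke_haemorrhagic_fraction: must be in [0, 1]")


def generate_epidemiology(
    spec: RateSpec | None = None,
    seed: int = 0,
    band_starts: Sequence[int] = EPI_BAND_STARTS,
    jitter_sd: float = 0.0,
) -> EpidemiologyTable:
    """Build an :class:`EpidemiologyTable` from rate curves.

    With ``jitter_sd`` 0 (the default) the table is the exact closed form
    of the curves; a positive value adds lognormal sampling noise to the
    rates (deterministic given ``seed``).
    """
    spec = spec or RateSpec()
    spec.validate()
    rng = np.random.default_rng(seed)
    rows = []
    idx = []
    for sex in SEXES:
        s = spec.for_sex(sex)
        for b in band_starts:
            mid = b + BAND_WIDTH / 2
            d = mid - 60.0
            row = {
                "ihd_incidence": s.ihd_at_60 * np.exp(s.ihd_log_slope * d),
                "stroke_incidence":
                    s.stroke_at_60 * np.exp(s.stroke_log_slope * d),
                "ihd_case_fatality":
                    float(np.clip(s.ihd_cf_at_60 + s.ihd_cf_slope * d, 0, 1)),
                "stroke_case_fatality": float(
                    np.clip(s.stroke_cf_at_60 + s.stroke_cf_slope * d, 0, 1)),
                "background_mortality":
                    s.mort_at_60 * np.exp(s.mort_log_slope * d),
                "ihd_trend": spec.ihd_trend,
                "stroke_trend": spec.stroke_trend,
                "stroke_haemorrhagic_fraction":
                    spec.stroke_haemorrhagic_fraction,
                "gi_bleed_incidence":
                    s.gi_bleed_at_60 * np.exp(s.gi_log_slope * d),
                "gi_bleed_case_fatality": spec.gi_bleed_case_fatality,
            }
            if jitter_sd > 0:
                for c in ("ihd_incidence", "stroke_incidence",
                          "background_mortality", "gi_bleed_incidence"):
                    row[c] *= float(rng.lognormal(0.0, jitter_sd))
            rows.append(row)
            idx.append((sex, b))
    frame = pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(idx, names=["sex", "age_band"]))
    table = EpidemiologyTable(frame)
    table.validate()
    return table


# ---------------------------------------------------------------------------
# Health-state weights and disease costs
# ---------------------------------------------------------------------------

@dataclass
class HealthStateWeights:
    """Disability and utility weights per state and age/sex.

    ``frame`` is indexed by ``(sex, age_band)`` with a
    ``background_disability`` column (average disability of the disease-free
    population, rising with age) and per-state ``disability_*`` columns.
    Utility weights default to the matched complement ``1 - disability``,
    so DALY-metric and QALY-metric streams coincide unless utilities are
    overridden.

    Combined weights are multiplicative: a person in the stroke state
    contributes ``(1 - background)(1 - d_stroke)`` healthy-equivalent
    years per person-year.
    """

    frame: pd.DataFrame
    gi_bleed_disability: float = 0.10   # acute, applied for the event year
    utilities: pd.DataFrame | None = None  # optional override, same shape

    STATE_COLS = ("disability_well", "disability_ihd", "disability_stroke")

    def validate(self) -> None:
        cols = ["background_disability", *self.STATE_COLS]
        missing = [c for c in cols if c not in self.frame.columns]
        if missing:
            raise DataError(f"health-state weights: missing columns {missing}")
        f = self.frame[cols]
        if ((f < 0) | (f > 1)).any().any():
            raise DataError("health-state weights: weight outside [0, 1]")
        if not 0 <= self.gi_bleed_disability <= 1:
            raise DataError("gi_bleed_disability outside [0, 1]")
        for c in self.STATE_COLS[1:]:
            if (self.frame[c] < self.frame["disability_well"]).any():
                raise DataError(
                    "health-state weights: well-state disability must not "
                    f"exceed disease-state disability ({c})")

    def healthy_weight(self, metric: str) -> pd.DataFrame:
        """Per-cell healthy-equivalent weight per person-year, one column
        per alive state (well, ihd, stroke)."""
        if metric == "QALY" and self.utilities is not None:
            return self.utilities.copy()
        bg = 1.0 - self.frame["background_disability"]
        out = pd.DataFrame(index=self.frame.index)
        for state, col in zip(("well", "ihd", "stroke"), self.STATE_COLS):
            out[state] = bg * (1.0 - self.frame[col])
        return out

    def gi_event_decrement(self, metric: str) -> pd.Series:
        """Healthy-equivalent years lost per (non-fatal or fatal) GI bleed
        event in the event year."""
        bg = 1.0 - self.frame["background_disability"]
        return bg * self.gi_bleed_disability


def default_health_state_weights(
    band_starts: Sequence[int] = EPI_BAND_STARTS,
) -> HealthStateWeights:
    """Plausible default weights: background disability rising with age,
    moderate IHD disability, larger stroke disability."""
    idx = pd.MultiIndex.from_product(
        [SEXES, list(band_starts)], names=["sex", "age_band"])
    mid = np.array([b + BAND_WIDTH / 2 for _, b in idx])
    frame = pd.DataFrame({
        "background_disability": np.clip(0.04 + 0.0022 * (mid - 35), 0, 0.6),
        "disability_well": 0.0,
        "disability_ihd": 0.14,
        "disability_stroke": 0.30,
    }, index=idx)
    weights = HealthStateWeights(frame=frame)
    weights.validate()
    return weights


@dataclass(frozen=True)
class DiseaseCostTable:
    """Treatment costs (2008 AUD per person) in the first year of illness
    and in each subsequent year; GI bleeds are acute (first-year only)."""

    first_year: Mapping[str, float] = field(default_factory=lambda: {
        "ihd": 9500.0, "stroke": 16000.0, "gi_bleed": 4500.0})
    subsequent_year: Mapping[str, float] = field(default_factory=lambda: {
        "ihd": 2100.0, "stroke": 4400.0, "gi_bleed": 0.0})

    def validate(self) -> None:
        for table, label in ((self.first_year, "first_year"),
                             (self.subsequent_year, "subsequent_year")):
            for disease in ("ihd", "stroke", "gi_bleed"):
                if disease not in table:
                    raise DataError(f"disease cost table: {label} missing "
                                    f"{disease}")
                if table[disease] < 0:
                    raise DataError(
                        f"disease cost table: {label}[{disease}] < 0")
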