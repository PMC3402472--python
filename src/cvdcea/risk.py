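"""Absolute cardiovascular risk: prediction, calibration, stratification.

Five-year first-event risk is predicted per individual from a
Framingham-style logistic equation; rather than re-deriving the original
cohort coefficients, predictions are multiplicatively scaled per age/sex
cell so that the mean calibrated prediction matches the observed 5-year
first-event probability.  Results therefore hinge on calibrated, not raw,
risk, and are insensitive to the precise placeholder coefficients.

The calibrated risk stratifies the eligible (no prior CVD) population
into absolute-risk bands (>=15%, 10-14%, 5-9% and the residual <5%) and
yields, per band and age/sex cell, the eligible count and the band's mean
risk relative to the cell mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .errors import (
    CalibrationError,
    ConfigurationError,
    DataError,
    EligibilityError,
)
from .interventions import RISK_BAND_LABELS
from .synthetic import (
    AGE_BAND_STARTS,
    EpidemiologyTable,
    IndividualRecord,
    SEXES,
    age_band,
)


@dataclass(frozen=True)
class RiskEquation:
    """Logistic 5-year CVD risk equation.

    ``logit(p) = intercept + b_age*(age-50) + b_male*[male]
    + b_smoker*[smoker] + b_tc*(tc-5.5) + b_hdl*(hdl-1.35)
    + b_diabetes*[diabetes] + b_sbp*(sbp-125)``

    The default coefficients are documented placeholders of plausible
    sign and magnitude; calibration to observed event rates absorbs their
    imprecision.  Monotonicity (increasing in age, SBP, cholesterol,
    smoking and diabetes; decreasing in HDL) holds whenever the
    coefficient signs are the defaults'.
    """

    intercept: float = -4.1
    b_age: float = 0.075
    b_male: float = 0.45
    b_smoker: float = 0.60
    b_tc: float = 0.30
    b_hdl: float = -0.65
    b_diabetes: float = 0.70
    b_sbp: float = 0.018
    link: Callable[[np.ndarray], np.ndarray] | None = None  # default expit
    horizon_years: int = 5

    def linear_predictor(self, frame: pd.DataFrame) -> np.ndarray:
        return (self.intercept
                + self.b_age * (frame["age"].to_numpy(float) - 50.0)
                + self.b_male * (frame["sex"].to_numpy() == "male")
                + self.b_smoker * frame["smoker"].to_numpy(bool)
                + self.b_tc * (frame["total_chol"].to_numpy(float) - 5.5)
                + self.b_hdl * (frame["hdl_chol"].to_numpy(float) - 1.35)
                + self.b_diabetes * frame["diabetes"].to_numpy(bool)
                + self.b_sbp * (frame["sbp"].to_numpy(float) - 125.0))

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        """Uncalibrated 5-year risk for each row of a survey frame."""
        lp = self.linear_predictor(frame)
        if self.link is not None:
            p = np.asarray(self.link(lp), dtype=float)
        else:
            p = 1.0 / (1.0 + np.exp(-lp))
        return p

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "intercept", "b_age", "b_male", "b_smoker", "b_tc", "b_hdl",
            "b_diabetes", "b_sbp", "horizon_years")}

    @classmethod
    def from_dict(cls, d: Mapping) -> "RiskEquation":
        return cls(**dict(d))


def default_risk_equation() -> RiskEquation:
    return RiskEquation()


@dataclass
class CalibrationFactors:
    """Multiplicative scale on predicted risk per (sex, age band), applied
    on the probability scale and capped at 1."""

    scales: pd.Series   # index (sex, age_band)

    def validate(self) -> None:
        if (self.scales <= 0).any():
            raise DataError("calibration scales must be > 0")

    def scale_for(self, sex: str, age: float) -> float:
        return float(self.scales.loc[(sex, age_band(age, AGE_BAND_STARTS))])

    @classmethod
    def identity(cls) -> "CalibrationFactors":
        idx = pd.MultiIndex.from_product(
            [SEXES, list(AGE_BAND_STARTS)], names=["sex", "age_band"])
        return cls(scales=pd.Series(1.0, index=idx))

    def to_frame(self) -> pd.DataFrame:
        return self.scales.rename("scale").reset_index()


def _record_frame(record: IndividualRecord) -> pd.DataFrame:
    return pd.DataFrame([{
        "age": record.age, "sex": record.sex, "smoker": record.smoker,
        "total_chol": record.total_chol, "hdl_chol": record.hdl_chol,
        "diabetes": record.diabetes, "sbp": record.sbp,
    }])


def predict_5yr_risk(
    record: IndividualRecord,
    eq: RiskEquation,
    cal: CalibrationFactors | None = None,
) -> float:
    """Calibrated (if factors given) 5-year first-event probability for
    one individual.  Individuals with prior CVD are not eligible."""
    if record.prior_cvd:
        raise EligibilityError(
            "risk prediction applies to primary prevention only: "
            "record has prior_cvd=True")
    p = float(eq.predict(_record_frame(record))[0])
    if cal is not None:
        p = min(1.0, cal.scale_for(record.sex, record.age) * p)
    return p


def predict_calibrated(
    survey: pd.DataFrame, eq: RiskEquation, cal: CalibrationFactors,
) -> np.ndarray:
    """Vectorized calibrated risk for every (non-prior-CVD) survey row."""
    p = eq.predict(survey)
    bands = np.minimum(survey["age"].to_numpy(float).astype(int) // 5 * 5,
                       AGE_BAND_STARTS[-1])
    scales = np.array([
        float(cal.scales.loc[(s, b)])
        for s, b in zip(survey["sex"].to_numpy(), bands)])
    return np.minimum(1.0, scales * p)


def _cell_scale(p: np.ndarray, target: float, tol: float = 1e-12) -> float:
    """Scale s with mean(min(1, s*p)) = target, by bisection once capping
    binds (the mean is continuous and nondecreasing in s)."""
    mean_p = p.mean()
    if target <= 0:
        return 1e-12 if mean_p > 0 else 1.0
    if mean_p == 0:
        raise CalibrationError("all predicted risks are zero in cell")
    s = target / mean_p
    if s * p.max() <= 1.0:
        return s
    if target >= 1.0:
        return 1.0 / p.min() if p.min() > 0 else np.inf
    lo, hi = 0.0, 1.0 / p.min() if p.min() > 0 else s
    while np.minimum(1.0, hi * p).mean() < target:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if np.minimum(1.0, mid * p).mean() < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(1.0, hi):
            break
    return 0.5 * (lo + hi)


def calibrate(
    survey: pd.DataFrame,
    eq: RiskEquation,
    observed: EpidemiologyTable,
) -> CalibrationFactors:
    """Scale factors per (sex, age band) such that the mean calibrated
    predicted risk in each cell equals the observed 5-year first-event
    probability (capped-scale fixed point, to 1e-9)."""
    eligible = survey.loc[~survey["prior_cvd"].astype(bool)]
    scales = {}
    for sex in SEXES:
        for b in AGE_BAND_STARTS:
            mask = (eligible["sex"] == sex) & \
                (eligible["age"].astype(int) // 5 * 5 == b)
            cell = eligible.loc[mask]
            if len(cell) == 0:
                raise CalibrationError(
                    f"calibration cell ({sex}, {b}) has no records")
            target = observed.five_year_first_event_prob(sex, b)
            p = eq.predict(cell)
            scales[(sex, b)] = _cell_scale(p, target)
    idx = pd.MultiIndex.from_tuples(scales.keys(), names=["sex", "age_band"])
    factors = CalibrationFactors(scales=pd.Series(
        list(scales.values()), index=idx))
    factors.validate()
    return factors


# ---------------------------------------------------------------------------
# Risk bands and stratification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RiskBandSpec:
    """Ordered 5-year risk thresholds defining the absolute-risk bands.

    Defaults give the bands >=15%, 10-14%, 5-9% and the residual <5%.
    Labels are ordered from least to most severe.
    """

    thresholds: tuple[float, ...] = (0.05, 0.10, 0.15)
    labels: tuple[str, ...] = RISK_BAND_LABELS

    def validate(self) -> None:
        t = self.thresholds
        if tuple(sorted(t)) != t or len(set(t)) != len(t):
            raise ConfigurationError("risk band thresholds must be "
                                     "strictly increasing")
        if not all(0 < x < 1 for x in t):
            raise ConfigurationError("risk band thresholds must be in (0,1)")
        if len(self.labels) != len(t) + 1:
            raise ConfigurationError(
                "need one more band label than thresholds")

    def band_of(self, p) -> np.ndarray:
        """Band label(s) for risk value(s) ``p``."""
        self.validate()
        idx = np.searchsorted(self.thresholds, np.atleast_1d(p),
                              side="right")
        out = np.asarray(self.labels, dtype=object)[idx]
        return out if np.ndim(p) else out[0]

    def severity(self, label: str) -> int:
        return self.labels.index(label)


@dataclass
class RiskStrata:
    """Eligible counts and relative risks per (sex, age band, risk band).

    ``frame`` is indexed by ``(sex, age_band, band)`` with columns
    ``eligible_count`` (survey counts), ``mean_risk`` and
    ``mean_relative_risk`` (band mean risk over the cell mean risk; the
    count-weighted mean of ``mean_relative_risk`` over bands is 1 in every
    cell).  ``prior_cvd_share`` per (sex, age_band) records the share of
    the cell excluded for prior CVD.
    """

    frame: pd.DataFrame
    prior_cvd_share: pd.Series
    bands: RiskBandSpec = field(default_factory=RiskBandSpec)

    def eligible_total(self) -> float:
        return float(self.frame["eligible_count"].sum())

    def cell(self, sex: str, band_start: int) -> pd.DataFrame:
        return self.frame.loc[(sex, band_start)]


def stratify(
    survey: pd.DataFrame,
    eq: RiskEquation,
    cal: CalibrationFactors,
    bands: RiskBandSpec | None = None,
) -> RiskStrata:
    """Partition the non-prior-CVD survey into risk bands per age/sex cell.

    Every eligible record lands in exactly one band; empty bands are kept
    with zero count and a relative risk of 0 so downstream joins stay
    rectangular.
    """
    bands = bands or RiskBandSpec()
    bands.validate()
    eligible = survey.loc[~survey["prior_cvd"].astype(bool)].copy()
    risk = predict_calibrated(eligible, eq, cal)
    eligible["risk"] = risk
    eligible["band"] = bands.band_of(risk)
    eligible["age_band"] = np.minimum(
        eligible["age"].astype(int) // 5 * 5, AGE_BAND_STARTS[-1])

    rows = []
    prior_share = {}
    for sex in SEXES:
        for b in AGE_BAND_STARTS:
            all_mask = (survey["sex"] == sex) & \
                (survey["age"].astype(int) // 5 * 5 == b)
            n_all = int(all_mask.sum())
            cell = eligible.loc[(eligible["sex"] == sex)
                                & (eligible["age_band"] == b)]
            prior_share[(sex, b)] = (
                1.0 - len(cell) / n_all if n_all else 0.0)
            cell_mean = cell["risk"].mean() if len(cell) else 0.0
            for label in bands.labels:
                grp = cell.loc[cell["band"] == label]
                mean_risk = float(grp["risk"].mean()) if len(grp) else 0.0
                rel = (mean_risk / cell_mean
                       if len(grp) and cell_mean > 0 else 0.0)
                rows.append({
                    "sex": sex, "age_band": b, "band": label,
                    "eligible_count": float(len(grp)),
                    "mean_risk": mean_risk,
                    "mean_relative_risk": rel,
                })
    frame = pd.DataFrame(rows).set_index(
        ["sex", "age_band", "band"]).sort_index()
    share = pd.Series(prior_share)
    share.index.names = ["sex", "age_band"]
    return RiskStrata(frame=frame, prior_cvd_share=share, bands=bands)


def coverage(
    strata: RiskStrata,
    gp_attendance: float,
    assessment_participation: float,
) -> float:
    """Reachable fraction of the eligible population through primary care:
    the product of annual GP attendance and GP participation in risk
    assessment, applied uniformly per cell.  Population-wide interventions
    bypass this (coverage 1 by construction)."""
    for name, v in (("gp_attendance", gp_attendance),
                    ("assessment_participation", assessment_participation)):
        if not 0 <= v <= 1:
            raise ConfigurationError(f"{name}: must be in [0, 1], got {v}")
    return gp_attendance * assessment_participation
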