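"""Four-state discrete-time Markov cohort model.

States are ``well`` (alive, no CVD history), ``ihd`` (alive after a first
ischaemic heart disease event), ``stroke`` (alive after a first stroke)
and the absorbing ``dead``.  Cycle length is one year; cohorts enter at
the midpoint of their 5-year age band in the reference year and are
simulated until extinction (or a configurable age cap).  Gastrointestinal
bleeds are acute events rather than a persistent state: each event incurs
a one-cycle cost and disability decrement and a per-event case fatality.

Within a cycle, competing first events (IHD, stroke, GI bleed, background
death) are resolved with the exponential competing-risks formula: the
combined exit probability ``1 - exp(-sum of hazards)`` is allocated to
causes proportionally to their hazard rates, which is exact under
constant within-cycle hazards.  Incidence and case fatality drift over
calendar time through annual trend multipliers.

Occupancy is recorded at the start of each cycle; person-years at risk
for a cycle are the start-of-cycle alive occupancy (no half-cycle
correction by default; a half-cycle option exists for sensitivity).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ModelError
from .synthetic import (
    BAND_WIDTH,
    DiseaseCostTable,
    EpidemiologyTable,
    HealthStateWeights,
)

STATES = ("well", "ihd", "stroke", "dead")
WELL, IHD, STROKE, DEAD = range(4)


@dataclass(frozen=True)
class DiscountSpec:
    """Annual discounting of future costs and health outcomes.

    Value in cycle ``t`` (0-based, cycle 0 = reference year) is weighted
    by ``(1 + rate) ** -t``.  Default rate 3%; 0% and 5% are the standard
    sensitivity settings.
    """

    rate: float = 0.03
    reference_year: int = 2008

    def __post_init__(self):
        if self.rate < 0:
            raise DataError(f"discount rate must be >= 0, got {self.rate}")

    def factors(self, n: int) -> np.ndarray:
        return (1.0 + self.rate) ** -np.arange(n, dtype=float)


def discounted_sum(stream, d: DiscountSpec | None = None) -> float:
    """Present value of a per-cycle stream: sum of value_t / (1+rate)^t,
    t counted from the reference year.  Rate 0 gives the plain sum; an
    empty stream gives 0."""
    arr = np.asarray(list(stream), dtype=float)
    if arr.size == 0:
        return 0.0
    d = d or DiscountSpec()
    return float(arr @ d.factors(arr.size))


@dataclass(frozen=True)
class MarkovConfig:
    """Engine settings.

    ``excess_mortality_*`` are additive annual death hazards in the
    post-event disease states on top of background mortality (first-ever
    event cohorts; recurrent events are not separately counted).
    ``unrelated_cost_per_life_year`` adds non-CVD health care costs in
    added years of life (a named sensitivity scenario; off by default).
    """

    age_cap: float = 110.0
    extinction_tol: float = 1e-9
    excess_mortality_ihd: float = 0.02
    excess_mortality_stroke: float = 0.045
    trend_enabled: bool = True
    half_cycle: bool = False
    unrelated_cost_per_life_year: float = 0.0
    reference_year: int = 2008


# ---------------------------------------------------------------------------
# Transition probabilities
# ---------------------------------------------------------------------------

def _well_exit(lam_i, lam_s, lam_g, mort):
    """Competing-risks allocation of the combined exit probability from
    the well state; returns per-cause probabilities (arrays ok)."""
    lam_i, lam_s = np.asarray(lam_i, float), np.asarray(lam_s, float)
    lam_g, mort = np.asarray(lam_g, float), np.asarray(mort, float)
    total = lam_i + lam_s + lam_g + mort
    p_exit = -np.expm1(-total)
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(total > 0, p_exit / np.where(total > 0, total, 1.0),
                         0.0)
    return lam_i * share, lam_s * share, lam_g * share, mort * share


def transition_matrix(
    age: float,
    sex: str,
    calendar_year: int,
    epi: EpidemiologyTable,
    rr_mods: Mapping[str, float] | None = None,
    config: MarkovConfig | None = None,
) -> np.ndarray:
    """Assemble the 4x4 one-cycle transition matrix for one age/sex cell.

    ``rr_mods`` scales incidence per channel (keys ``ihd``, ``stroke``,
    ``gi_bleed``; default 1).  Incidence and case fatality are scaled by
    ``trend ** (calendar_year - reference_year)``.  Rows sum to 1.
    """
    config = config or MarkovConfig()
    rr = {"ihd": 1.0, "stroke": 1.0, "gi_bleed": 1.0, **(rr_mods or {})}
    for k, v in rr.items():
        if v <= 0:
            raise ModelError(f"rr_mods[{k}] must be > 0, got {v}")
    cell = epi.cell(sex, age)
    t = (calendar_year - config.reference_year) if config.trend_enabled else 0
    tr_i = float(cell.ihd_trend) ** t
    tr_s = float(cell.stroke_trend) ** t
    lam_i = float(cell.ihd_incidence) * tr_i * rr["ihd"]
    lam_s = float(cell.stroke_incidence) * tr_s * rr["stroke"]
    lam_g = float(cell.gi_bleed_incidence) * rr["gi_bleed"]
    mort = float(cell.background_mortality)
    cf_i = min(1.0, float(cell.ihd_case_fatality) * tr_i)
    cf_s = min(1.0, float(cell.stroke_case_fatality) * tr_s)
    cf_g = float(cell.gi_bleed_case_fatality)

    p_i, p_s, p_g, p_m = _well_exit(lam_i, lam_s, lam_g, mort)
    m = np.zeros((4, 4))
    m[WELL, IHD] = p_i * (1.0 - cf_i)
    m[WELL, STROKE] = p_s * (1.0 - cf_s)
    m[WELL, DEAD] = p_i * cf_i + p_s * cf_s + p_g * cf_g + p_m
    m[WELL, WELL] = 1.0 - m[WELL, IHD] - m[WELL, STROKE] - m[WELL, DEAD]
    p_die_ihd = -np.expm1(-(mort + config.excess_mortality_ihd))
    p_die_str = -np.expm1(-(mort + config.excess_mortality_stroke))
    m[IHD, DEAD] = p_die_ihd
    m[IHD, IHD] = 1.0 - p_die_ihd
    m[STROKE, DEAD] = p_die_str
    m[STROKE, STROKE] = 1.0 - p_die_str
    m[DEAD, DEAD] = 1.0
    if (m < -1e-15).any() or (m > 1 + 1e-15).any():
        raise ModelError(
            f"transition probability outside [0, 1] for cell "
            f"({sex}, age {age}), year {calendar_year}")
    return m


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class CohortTrace:
    """Per-cycle record of one simulated cohort (or unit).

    ``occupancy[t]`` is start-of-cycle occupancy over (well, ihd, stroke,
    dead); events are counts of incident first events within cycle ``t``.
    ``life_years`` uses the start-of-cycle person-years-at-risk
    convention.  Cost streams are undiscounted 2008 AUD.
    """

    sex: str
    entry_age: float
    size: float
    sim_year: np.ndarray          # 1-based simulation year per cycle
    age: np.ndarray
    occupancy: np.ndarray         # (T, 4)
    events_ihd: np.ndarray
    events_stroke: np.ndarray
    events_gi: np.ndarray
    deaths: np.ndarray
    life_years: np.ndarray
    haly_daly: np.ndarray
    haly_qaly: np.ndarray
    disease_cost: np.ndarray
    cost_gov: np.ndarray
    cost_patient: np.ndarray

    def validate(self) -> None:
        occ = self.occupancy
        if (occ < -1e-9).any():
            raise ModelError("negative occupancy in trace")
        tot = occ.sum(axis=1)
        if not np.allclose(tot, self.size, atol=1e-9 * max(self.size, 1.0)):
            raise ModelError("occupancy does not sum to cohort size")
        if (np.diff(occ[:, DEAD]) < -1e-9).any():
            raise ModelError("dead occupancy must be non-decreasing")

    def to_frame(self) -> pd.DataFrame:
        f = pd.DataFrame({
            "sim_year": self.sim_year, "age": self.age,
            "well": self.occupancy[:, WELL],
            "ihd": self.occupancy[:, IHD],
            "stroke": self.occupancy[:, STROKE],
            "dead": self.occupancy[:, DEAD],
            "events_ihd": self.events_ihd,
            "events_stroke": self.events_stroke,
            "events_gi": self.events_gi,
            "deaths": self.deaths,
            "life_years": self.life_years,
            "haly_daly": self.haly_daly,
            "haly_qaly": self.haly_qaly,
            "disease_cost": self.disease_cost,
            "cost_gov": self.cost_gov,
            "cost_patient": self.cost_patient,
        })
        f.attrs["sex"] = self.sex
        f.attrs["entry_age"] = self.entry_age
        f.attrs["size"] = self.size
        return f


class PopulationTrace:
    """Stacked traces for many cohorts simulated in lockstep.

    All stream arrays have shape ``(T, n_units)``; ``occupancy`` has shape
    ``(T, n_units, 4)``.  ``totals`` discounts and sums every stream.
    """

    def __init__(self, units: pd.DataFrame, arrays: dict[str, np.ndarray]):
        self.units = units
        for k, v in arrays.items():
            setattr(self, k, v)
        self.n_cycles = arrays["life_years"].shape[0]

    STREAMS = ("life_years", "haly_daly", "haly_qaly", "disease_cost",
               "cost_gov", "cost_patient", "events_ihd", "events_stroke",
               "events_gi", "deaths")

    def totals(self, discount: DiscountSpec | None = None) -> dict[str, float]:
        d = discount or DiscountSpec()
        df = d.factors(self.n_cycles)
        out = {}
        for name in self.STREAMS:
            out[name] = float(df @ getattr(self, name).sum(axis=1))
        return out

    def unit_trace(self, i: int) -> CohortTrace:
        u = self.units.iloc[i]
        return CohortTrace(
            sex=u["sex"], entry_age=float(u["entry_age"]),
            size=float(u["size"]),
            sim_year=np.arange(1, self.n_cycles + 1),
            age=float(u["entry_age"]) + np.arange(self.n_cycles, dtype=float),
            occupancy=self.occupancy[:, i, :],
            events_ihd=self.events_ihd[:, i],
            events_stroke=self.events_stroke[:, i],
            events_gi=self.events_gi[:, i],
            deaths=self.deaths[:, i],
            life_years=self.life_years[:, i],
            haly_daly=self.haly_daly[:, i],
            haly_qaly=self.haly_qaly[:, i],
            disease_cost=self.disease_cost[:, i],
            cost_gov=self.cost_gov[:, i],
            cost_patient=self.cost_patient[:, i])


def _epi_arrays(epi: EpidemiologyTable):
    """Dense numpy view of the epidemiology table: arrays indexed by
    (sex_idx, band_idx).  Memoised on the table object; do not mutate a
    table's frame in place after simulating with it."""
    cached = getattr(epi, "_dense_cache", None)
    if cached is not None:
        return cached
    frame = epi.frame
    sexes = ("male", "female")
    bands = sorted({b for _, b in frame.index})
    nb = len(bands)
    cols = {}
    for c in frame.columns:
        arr = np.zeros((2, nb))
        for si, sex in enumerate(sexes):
            arr[si, :] = frame.loc[sex].reindex(bands)[c].to_numpy(float)
        cols[c] = arr
    result = (cols, np.array(bands))
    object.__setattr__(epi, "_dense_cache", result)
    return result


def _weight_arrays(weights: HealthStateWeights, bands: np.ndarray):
    cached = getattr(weights, "_dense_cache", None)
    if cached is not None and cached[0].shape[1] == len(bands):
        return cached[1]
    idx_frames = {}
    for metric in ("DALY", "QALY"):
        hw = weights.healthy_weight(metric)
        arr = np.zeros((2, len(bands), 3))
        dec = np.zeros((2, len(bands)))
        gdec = weights.gi_event_decrement(metric)
        for si, sex in enumerate(("male", "female")):
            sub = hw.loc[sex].reindex(bands)
            arr[si] = sub[["well", "ihd", "stroke"]].to_numpy(float)
            dec[si] = gdec.loc[sex].reindex(bands).to_numpy(float)
        idx_frames[metric] = (arr, dec)
    object.__setattr__(weights, "_dense_cache",
                       (idx_frames["DALY"][0], idx_frames))
    return idx_frames


def simulate_units(
    units: pd.DataFrame,
    epi: EpidemiologyTable,
    weights: HealthStateWeights,
    cost_table: DiseaseCostTable,
    rr_fn: Callable[[int], np.ndarray] | None = None,
    int_cost_fn: Callable[[int, np.ndarray], tuple] | None = None,
    config: MarkovConfig | None = None,
) -> PopulationTrace:
    """Simulate many cohorts in lockstep until extinction.

    ``units`` needs columns ``entry_age``, ``sex``, ``size`` and
    optionally ``rel_risk`` (baseline-risk multiplier on cell incidence,
    default 1).  ``rr_fn(sim_year)`` returns per-unit effective relative
    risks as an ``(n_units, 3)`` array over (ihd, stroke, gi_bleed);
    ``int_cost_fn(sim_year, alive_fraction)`` returns per-unit
    (government, patient) intervention cost totals for the cycle.
    """
    config = config or MarkovConfig()
    cost_table.validate()
    n = len(units)
    entry_age = units["entry_age"].to_numpy(float)
    size = units["size"].to_numpy(float)
    rel = (units["rel_risk"].to_numpy(float)
           if "rel_risk" in units.columns else np.ones(n))
    sex_idx = (units["sex"].to_numpy() == "female").astype(int)

    cols, bands = _epi_arrays(epi)
    wmaps = _weight_arrays(weights, bands)
    c1 = cost_table.first_year
    c2 = cost_table.subsequent_year

    max_cycles = int(np.ceil(config.age_cap - entry_age.min())) + 1
    occ = np.zeros((n, 4))
    occ[:, WELL] = size
    streams: dict[str, list[np.ndarray]] = {
        k: [] for k in (*PopulationTrace.STREAMS,)}
    occ_hist: list[np.ndarray] = []

    for t in range(max_cycles):
        age = entry_age + t
        active = (age < config.age_cap) & \
            (occ[:, :3].sum(axis=1) > config.extinction_tol * size)
        if not active.any():
            break
        band_idx = np.clip(((np.floor(age) - bands[0]) // BAND_WIDTH)
                           .astype(int), 0, len(bands) - 1)

        def cell(c):
            return cols[c][sex_idx, band_idx]

        tr_i = cell("ihd_trend") ** t if config.trend_enabled else 1.0
        tr_s = cell("stroke_trend") ** t if config.trend_enabled else 1.0
        rr = rr_fn(t + 1) if rr_fn is not None else np.ones((n, 3))
        rr = np.asarray(rr, float)
        lam_i = cell("ihd_incidence") * tr_i * rel * rr[:, 0]
        lam_s = cell("stroke_incidence") * tr_s * rel * rr[:, 1]
        lam_g = cell("gi_bleed_incidence") * rr[:, 2]
        mort = cell("background_mortality")
        cf_i = np.minimum(1.0, cell("ihd_case_fatality") * tr_i)
        cf_s = np.minimum(1.0, cell("stroke_case_fatality") * tr_s)
        cf_g = cell("gi_bleed_case_fatality")
        lam_i = np.where(active, lam_i, 0.0)
        lam_s = np.where(active, lam_s, 0.0)
        lam_g = np.where(active, lam_g, 0.0)
        mort_eff = np.where(active, mort, 0.0)

        p_i, p_s, p_g, p_m = _well_exit(lam_i, lam_s, lam_g, mort_eff)
        well = occ[:, WELL]
        e_i = well * p_i
        e_s = well * p_s
        e_g = well * p_g
        p_die_ihd = np.where(active, -np.expm1(
            -(mort + config.excess_mortality_ihd)), 0.0)
        p_die_str = np.where(active, -np.expm1(
            -(mort + config.excess_mortality_stroke)), 0.0)

        deaths = (e_i * cf_i + e_s * cf_s + e_g * cf_g + well * p_m
                  + occ[:, IHD] * p_die_ihd + occ[:, STROKE] * p_die_str)
        new_occ = np.empty_like(occ)
        new_occ[:, WELL] = well - e_i - e_s - e_g * cf_g - well * p_m
        new_occ[:, IHD] = occ[:, IHD] * (1 - p_die_ihd) + e_i * (1 - cf_i)
        new_occ[:, STROKE] = (occ[:, STROKE] * (1 - p_die_str)
                              + e_s * (1 - cf_s))
        new_occ[:, DEAD] = occ[:, DEAD] + deaths

        occ_use = 0.5 * (occ + new_occ) if config.half_cycle else occ
        alive = np.where(active, occ_use[:, :3].sum(axis=1), 0.0)
        w_d, gdec_d = wmaps["DALY"]
        w_q, gdec_q = wmaps["QALY"]
        wd = w_d[sex_idx, band_idx]       # (n, 3)
        wq = w_q[sex_idx, band_idx]
        haly_d = (occ_use[:, :3] * wd).sum(axis=1) \
            - e_g * gdec_d[sex_idx, band_idx]
        haly_q = (occ_use[:, :3] * wq).sum(axis=1) \
            - e_g * gdec_q[sex_idx, band_idx]
        haly_d = np.where(active, haly_d, 0.0)
        haly_q = np.where(active, haly_q, 0.0)

        dis_cost = (e_i * c1["ihd"] + occ[:, IHD] * c2["ihd"]
                    + e_s * c1["stroke"] + occ[:, STROKE] * c2["stroke"]
                    + e_g * c1["gi_bleed"])
        dis_cost = np.where(active, dis_cost, 0.0)
        if config.unrelated_cost_per_life_year:
            dis_cost = dis_cost + alive * config.unrelated_cost_per_life_year

        if int_cost_fn is not None:
            alive_frac = np.where(size > 0, alive / np.where(size > 0, size,
                                                             1.0), 0.0)
            gov, pat = int_cost_fn(t + 1, alive_frac)
        else:
            gov = pat = np.zeros(n)

        occ_hist.append(occ.copy())
        streams["life_years"].append(alive)
        streams["haly_daly"].append(haly_d)
        streams["haly_qaly"].append(haly_q)
        streams["disease_cost"].append(dis_cost)
        streams["cost_gov"].append(np.asarray(gov, float))
        streams["cost_patient"].append(np.asarray(pat, float))
        streams["events_ihd"].append(e_i)
        streams["events_stroke"].append(e_s)
        streams["events_gi"].append(e_g)
        streams["deaths"].append(deaths)
        occ = new_occ

    arrays = {k: (np.array(v) if v else np.zeros((0, n)))
              for k, v in streams.items()}
    arrays["occupancy"] = (np.array(occ_hist) if occ_hist
                           else np.zeros((0, n, 4)))
    return PopulationTrace(units.reset_index(drop=True), arrays)


def simulate_cohort(
    size: float,
    entry_age: float,
    sex: str,
    epi: EpidemiologyTable,
    weights: HealthStateWeights,
    cost_table: DiseaseCostTable,
    rr_schedule: Callable[[int], Sequence[float]] | None = None,
    intervention_cost: Callable[[int, float], tuple] | None = None,
    config: MarkovConfig | None = None,
) -> CohortTrace:
    """Simulate one age/sex cohort until extinction.

    ``rr_schedule(sim_year)`` returns (rr_ihd, rr_stroke, rr_gi_bleed);
    ``intervention_cost(sim_year, alive_fraction)`` returns the cohort's
    (government, patient) cost for the cycle.
    """
    units = pd.DataFrame({"entry_age": [entry_age], "sex": [sex],
                          "size": [float(size)]})
    rr_fn = None
    if rr_schedule is not None:
        def rr_fn(y):  # noqa: F811 - deliberate closure
            return np.asarray(rr_schedule(y), float).reshape(1, 3)
    cost_fn = None
    if intervention_cost is not None:
        def cost_fn(y, alive_frac):
            gov, pat = intervention_cost(y, float(alive_frac[0]))
            return np.array([gov]), np.array([pat])
    trace = simulate_units(units, epi, weights, cost_table, rr_fn, cost_fn,
                           config).unit_trace(0)
    trace.validate()
    return trace


# ---------------------------------------------------------------------------
# Standalone stream computations (same formulas as the simulator)
# ---------------------------------------------------------------------------

def health_adjusted_years(
    trace: CohortTrace, weights: HealthStateWeights, metric: str = "DALY",
) -> np.ndarray:
    """Healthy-equivalent life-year stream for a trace.

    Per cycle: occupancy in each alive state times that state's healthy
    weight (the multiplicative complement of background and state
    disability for the DALY metric; utilities for QALY), minus the acute
    GI-bleed decrement per event.  With all-zero disability (or all-one
    utility) the stream equals the life-year stream.
    """
    if metric not in ("DALY", "QALY"):
        raise DataError(f"unsupported metric {metric!r}")
    weights.validate()
    hw = weights.healthy_weight(metric)
    gdec = weights.gi_event_decrement(metric)
    out = np.zeros(len(trace.sim_year))
    for t, age in enumerate(trace.age):
        b = int(np.floor(age)) - int(np.floor(age)) % BAND_WIDTH
        b = min(max(b, hw.loc[trace.sex].index.min()),
                hw.loc[trace.sex].index.max())
        w = hw.loc[(trace.sex, b)]
        out[t] = (trace.occupancy[t, WELL] * w["well"]
                  + trace.occupancy[t, IHD] * w["ihd"]
                  + trace.occupancy[t, STROKE] * w["stroke"]
                  - trace.events_gi[t] * float(gdec.loc[(trace.sex, b)]))
    return out


def disease_costs(
    trace: CohortTrace, cost_table: DiseaseCostTable,
) -> np.ndarray:
    """Treatment-cost stream: incident events charged the first-year
    cost, prevalent survivors the subsequent-year cost, GI bleeds per
    event."""
    cost_table.validate()
    c1, c2 = cost_table.first_year, cost_table.subsequent_year
    return (trace.events_ihd * c1["ihd"]
            + trace.occupancy[:, IHD] * c2["ihd"]
            + trace.events_stroke * c1["stroke"]
            + trace.occupancy[:, STROKE] * c2["stroke"]
            + trace.events_gi * c1["gi_bleed"])
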