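"""Shared fixtures.

The default model context is expensive enough to share: it is built once
per session at the default survey size and reused by every test that
needs the full pipeline (risk calibration, stratified units,
back-calculated null).
"""

import numpy as np
import pandas as pd
import pytest

import cvdcea as c


@pytest.fixture(scope="session")
def ctx():
    """Default synthetic-population context (full analysis settings)."""
    return c.build_default_context(seed=1, n_per_cell=250)


@pytest.fixture(scope="session")
def null_totals(ctx):
    return ctx.null_totals()


@pytest.fixture()
def flat_epi():
    """Epidemiology table with constant background mortality and no
    disease, for closed-form life-expectancy checks."""
    return make_epi(background_mortality=0.02)


def make_epi(
    ihd=0.0, stroke=0.0, background_mortality=0.0,
    ihd_cf=0.0, stroke_cf=0.0, gi=0.0, gi_cf=0.0,
    ihd_trend=1.0, stroke_trend=1.0, haem_fraction=0.2,
):
    """Hand-built epidemiology table, constant over all age/sex cells."""
    idx = pd.MultiIndex.from_product(
        [list(c.SEXES), list(c.EPI_BAND_STARTS)], names=["sex", "age_band"])
    frame = pd.DataFrame({
        "ihd_incidence": ihd, "stroke_incidence": stroke,
        "ihd_case_fatality": ihd_cf, "stroke_case_fatality": stroke_cf,
        "background_mortality": background_mortality,
        "ihd_trend": ihd_trend, "stroke_trend": stroke_trend,
        "stroke_haemorrhagic_fraction": haem_fraction,
        "gi_bleed_incidence": gi, "gi_bleed_case_fatality": gi_cf,
    }, index=idx)
    table = c.EpidemiologyTable(frame)
    table.validate()
    return table


def make_weights(bg=0.0, ihd=0.0, stroke=0.0, gi=0.0):
    idx = pd.MultiIndex.from_product(
        [list(c.SEXES), list(c.EPI_BAND_STARTS)], names=["sex", "age_band"])
    frame = pd.DataFrame({
        "background_disability": bg, "disability_well": 0.0,
        "disability_ihd": ihd, "disability_stroke": stroke,
    }, index=idx)
    w = c.HealthStateWeights(frame=frame, gi_bleed_disability=gi)
    w.validate()
    return w


def zero_cost_table():
    return c.DiseaseCostTable(
        first_year={"ihd": 0.0, "stroke": 0.0, "gi_bleed": 0.0},
        subsequent_year={"ihd": 0.0, "stroke": 0.0, "gi_bleed": 0.0})


@pytest.fixture()
def record():
    return c.IndividualRecord(
        age=55.0, sex="male", smoker=False, total_chol=5.5, hdl_chol=1.3,
        diabetes=False, sbp=130.0, prior_cvd=False)
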