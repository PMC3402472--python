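"""Markov cohort engine: transition assembly, simulation, oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cvdcea as c
from cvdcea.markov import DEAD, IHD, STROKE, WELL
from conftest import make_epi, make_weights, zero_cost_table


def no_excess(**kw):
    return c.MarkovConfig(excess_mortality_ihd=0.0,
                          excess_mortality_stroke=0.0, **kw)


class TestTransitionMatrix:
    def test_no_hazards_gives_identity(self):
        epi = make_epi()
        m = c.transition_matrix(60, "male", 2008, epi, config=no_excess())
        assert np.allclose(m, np.eye(4), atol=1e-15)

    def test_rows_sum_to_one(self):
        epi = make_epi(ihd=0.02, stroke=0.01, background_mortality=0.01,
                       ihd_cf=0.3, stroke_cf=0.25, gi=0.002, gi_cf=0.05)
        m = c.transition_matrix(72, "female", 2015, epi)
        assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)
        assert m[DEAD, DEAD] == 1.0

    def test_unit_rr_mods_equal_do_nothing_matrix(self):
        epi = make_epi(ihd=0.02, stroke=0.01, background_mortality=0.01)
        base = c.transition_matrix(60, "male", 2010, epi)
        modded = c.transition_matrix(
            60, "male", 2010, epi,
            rr_mods={"ihd": 1.0, "stroke": 1.0, "gi_bleed": 1.0})
        assert np.array_equal(base, modded)

    def test_trend_closed_form_matches_yearly_accumulation(self):
        epi = make_epi(ihd=0.02, ihd_trend=0.98)
        years = 10
        m = c.transition_matrix(60, "male", 2008 + years, epi,
                                config=no_excess())
        mult = 1.0
        for _ in range(years):
            mult *= 0.98
        lam = 0.02 * mult
        expected = lam / lam * -np.expm1(-lam)   # single hazard
        assert m[WELL, IHD] + m[WELL, DEAD] == pytest.approx(expected,
                                                             abs=1e-12)
        assert mult == pytest.approx(0.98 ** years, abs=1e-12)

    def test_nonpositive_rr_mod_raises(self):
        with pytest.raises(c.ModelError):
            c.transition_matrix(60, "male", 2008, make_epi(),
                                rr_mods={"ihd": 0.0})


class TestSimulateCohort:
    def test_empty_cohort_gives_zero_trace(self):
        trace = c.simulate_cohort(0.0, 37.5, "male", make_epi(ihd=0.01),
                                  make_weights(), c.DiseaseCostTable())
        assert np.allclose(trace.occupancy, 0.0)
        assert trace.life_years.sum() == 0.0

    def test_constant_hazard_life_expectancy_closed_form(self, flat_epi):
        m = 0.02
        p = -math.expm1(-m)
        q = 1.0 - p
        rate = 0.03
        trace = c.simulate_cohort(
            1000.0, 37.5, "male", flat_epi, make_weights(),
            zero_cost_table(), config=no_excess())
        T = len(trace.life_years)
        x = q / (1 + rate)
        expected = 1000.0 * (1 - x ** T) / (1 - x)   # truncated geometric
        got = c.discounted_sum(trace.life_years, c.DiscountSpec(rate=rate))
        assert got == pytest.approx(expected, abs=1e-9 * expected)

    def test_two_state_toy_three_cycle_hand_enumeration(self, flat_epi):
        # survival 0.9 per cycle: occupancy 1000, 900, 810 exactly
        epi = make_epi(background_mortality=-math.log(0.9))
        trace = c.simulate_cohort(1000.0, 37.5, "male", epi, make_weights(),
                                  zero_cost_table(), config=no_excess())
        well = trace.occupancy[:3, WELL]
        assert well == pytest.approx([1000.0, 900.0, 810.0], abs=1e-9)

    def test_conservation_and_absorbing_dead(self, ctx):
        trace = c.simulate_cohort(
            5000.0, 62.5, "female", ctx.epi_observed, ctx.weights,
            ctx.cost_table)
        trace.validate()
        assert np.allclose(trace.occupancy.sum(axis=1), 5000.0, atol=1e-6)
        assert (np.diff(trace.occupancy[:, DEAD]) >= -1e-9).all()

    def test_path_enumeration_oracle_three_cycles(self):
        """Matrix simulation equals exhaustive enumeration over all state
        sequences for the first three cycles."""
        epi = make_epi(ihd=0.03, stroke=0.02, background_mortality=0.015,
                       ihd_cf=0.3, stroke_cf=0.35, gi=0.004, gi_cf=0.1,
                       ihd_trend=0.98, stroke_trend=1.01)
        cfg = c.MarkovConfig()
        mats = [np.asarray(c.transition_matrix(37.5 + t, "male", 2008 + t,
                                               epi, config=cfg))
                for t in range(3)]
        size = 1234.0
        # enumerate every path (s0=well, s1, s2, s3)
        occ = {t: np.zeros(4) for t in range(4)}
        occ[0][WELL] = size
        for s1, s2, s3 in itertools.product(range(4), repeat=3):
            pr = mats[0][WELL, s1] * mats[1][s1, s2] * mats[2][s2, s3]
            occ[3][s3] += size * pr
        for s1, s2 in itertools.product(range(4), repeat=2):
            occ[2][s2] += size * mats[0][WELL, s1] * mats[1][s1, s2]
        for s1 in range(4):
            occ[1][s1] += size * mats[0][WELL, s1]

        trace = c.simulate_cohort(size, 37.5, "male", epi, make_weights(),
                                  zero_cost_table(), config=cfg)
        for t in range(4):
            if t < len(trace.occupancy):
                assert trace.occupancy[t] == pytest.approx(
                    occ[t], abs=1e-12 * size)

    def test_null_rr_schedule_equals_do_nothing(self, ctx):
        base = c.simulate_cohort(1000.0, 52.5, "male", ctx.epi_observed,
                                 ctx.weights, ctx.cost_table)
        nulled = c.simulate_cohort(
            1000.0, 52.5, "male", ctx.epi_observed, ctx.weights,
            ctx.cost_table, rr_schedule=lambda y: (1.0, 1.0, 1.0),
            intervention_cost=lambda y, alive: (0.0, 0.0))
        assert np.array_equal(base.occupancy, nulled.occupancy)
        assert np.array_equal(base.disease_cost, nulled.disease_cost)

    def test_lower_rr_never_decreases_health(self, ctx):
        def haly(rr):
            t = c.simulate_cohort(
                1000.0, 57.5, "male", ctx.epi_observed, ctx.weights,
                ctx.cost_table, rr_schedule=lambda y: (rr, 1.0, 1.0))
            return c.discounted_sum(t.haly_daly, ctx.discount)
        values = [haly(rr) for rr in (1.0, 0.8, 0.6, 0.4)]
        assert all(b >= a - 1e-9 for a, b in zip(values, values[1:]))


class TestHealthAdjustedYears:
    def test_zero_disability_equals_life_years(self, flat_epi):
        trace = c.simulate_cohort(1000.0, 37.5, "male", flat_epi,
                                  make_weights(), zero_cost_table())
        stream = c.health_adjusted_years(trace, make_weights(), "DALY")
        assert stream == pytest.approx(trace.life_years, abs=1e-9)

    def test_stroke_disability_weights_person_years(self):
        w = make_weights(stroke=0.3)
        epi = make_epi()   # no transitions: occupancy frozen
        trace = c.simulate_cohort(100.0, 37.5, "male", epi, w,
                                  zero_cost_table(), config=no_excess())
        # move everyone to the stroke state by hand
        trace.occupancy[:, STROKE] = trace.occupancy[:, WELL]
        trace.occupancy[:, WELL] = 0.0
        stream = c.health_adjusted_years(trace, w, "DALY")
        assert stream == pytest.approx(0.7 * trace.life_years, rel=1e-12)

    def test_matched_weights_daly_equals_qaly(self, ctx):
        trace = c.simulate_cohort(1000.0, 47.5, "female", ctx.epi_observed,
                                  ctx.weights, ctx.cost_table)
        d = c.health_adjusted_years(trace, ctx.weights, "DALY")
        q = c.health_adjusted_years(trace, ctx.weights, "QALY")
        assert d == pytest.approx(q, rel=1e-12)

    def test_unknown_metric_raises(self, flat_epi):
        trace = c.simulate_cohort(10.0, 37.5, "male", flat_epi,
                                  make_weights(), zero_cost_table())
        with pytest.raises(c.DataError):
            c.health_adjusted_years(trace, make_weights(), "HALE")


class TestDiscounting:
    def test_zero_rate_plain_sum(self):
        assert c.discounted_sum([1, 1, 1], c.DiscountSpec(rate=0.0)) == 3.0

    def test_annuity_closed_form(self):
        d = c.DiscountSpec(rate=0.03)
        got = c.discounted_sum(np.ones(10), d)
        expected = (1 - 1.03 ** -10) / (1 - 1.03 ** -1) * 1.03 ** 0
        # geometric series sum_{t=0}^{9} 1.03^-t
        expected = sum(1.03 ** -t for t in range(10))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_empty_stream_is_zero(self):
        assert c.discounted_sum([], c.DiscountSpec()) == 0.0

    @settings(max_examples=40, derandomize=True)
    @given(st.lists(st.floats(0, 100), min_size=1, max_size=20),
           st.floats(0, 0.1), st.floats(0, 0.1))
    def test_higher_rate_never_increases_total(self, stream, r1, r2):
        lo, hi = sorted([r1, r2])
        assert c.discounted_sum(stream, c.DiscountSpec(rate=hi)) <= \
            c.discounted_sum(stream, c.DiscountSpec(rate=lo)) + 1e-9

    def test_negative_rate_rejected(self):
        with pytest.raises(c.DataError):
            c.DiscountSpec(rate=-0.01)


class TestDiseaseCosts:
    def test_no_events_zero_stream(self, flat_epi):
        trace = c.simulate_cohort(1000.0, 37.5, "male", flat_epi,
                                  make_weights(), c.DiseaseCostTable())
        stream = c.disease_costs(trace, c.DiseaseCostTable())
        assert np.allclose(stream, 0.0)

    def test_incident_then_survivor_bookkeeping(self):
        """10 incident strokes in cycle 1, 8 surviving into cycle 2:
        costs are 10*c1 then 8*c2."""
        table = c.DiseaseCostTable(
            first_year={"ihd": 0, "stroke": 500.0, "gi_bleed": 0},
            subsequent_year={"ihd": 0, "stroke": 120.0, "gi_bleed": 0})
        trace = c.simulate_cohort(10.0, 37.5, "male", make_epi(),
                                  make_weights(), table,
                                  config=no_excess())
        trace.events_stroke[:] = 0.0
        trace.events_stroke[0] = 10.0
        trace.occupancy[:, STROKE] = 0.0
        trace.occupancy[1:, STROKE] = 8.0
        stream = c.disease_costs(trace, table)
        assert stream[0] == pytest.approx(10 * 500.0)
        assert stream[1] == pytest.approx(8 * 120.0)

    def test_costs_linear_in_cohort_size(self, ctx):
        small = c.simulate_cohort(1000.0, 57.5, "male", ctx.epi_observed,
                                  ctx.weights, ctx.cost_table)
        big = c.simulate_cohort(2000.0, 57.5, "male", ctx.epi_observed,
                                ctx.weights, ctx.cost_table)
        assert big.disease_cost == pytest.approx(2 * small.disease_cost,
                                                 rel=1e-12)

    def test_missing_disease_raises(self, flat_epi):
        trace = c.simulate_cohort(10.0, 37.5, "male", flat_epi,
                                  make_weights(), c.DiseaseCostTable())
        bad = c.DiseaseCostTable(first_year={"ihd": 1.0},
                                 subsequent_year={"ihd": 1.0})
        with pytest.raises(c.DataError):
            c.disease_costs(trace, bad)
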