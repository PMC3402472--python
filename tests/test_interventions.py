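"""Effect algebra, adherence, costs and parameter sampling."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cvdcea as c
from cvdcea.interventions import ParamUncertainty


class TestRiskFactorToRR:
    @pytest.mark.parametrize("delta,expected", [
        (0.0, (1.0, 1.0)),
        (1.0, (0.966, 0.937)),          # 3.4% IHD, 6.3% stroke per 1% SBP
        (2.6, (0.9116, 0.8362)),        # lifestyle-program SBP effect
    ])
    def test_sbp_linear_rule(self, delta, expected):
        rr = c.rr_from_sbp_pct(delta)
        assert rr[0] == pytest.approx(expected[0], abs=1e-12)
        assert rr[1] == pytest.approx(expected[1], abs=1e-12)

    @pytest.mark.parametrize("delta,expected", [
        (1.0, (0.982, 0.992)),          # 1.8% IHD, 0.80% stroke per 1% TC
        (7.5, (0.865, 0.940)),          # phytosterol effect
    ])
    def test_tc_linear_rule(self, delta, expected):
        rr = c.rr_from_tc_pct(delta)
        assert rr[0] == pytest.approx(expected[0], abs=1e-12)
        assert rr[1] == pytest.approx(expected[1], abs=1e-12)

    def test_cholesterol_increase_is_harm(self):
        # community program cholesterol effect is -0.51% (an increase)
        rr_i, rr_s = c.rr_from_tc_pct(-0.51)
        assert rr_i > 1.0 and rr_s > 1.0

    def test_out_of_range_delta_raises(self):
        with pytest.raises(c.DomainError):
            c.rr_from_sbp_pct(100.0)

    def test_rr_floor_prevents_nonpositive(self):
        rr_i, rr_s = c.rr_from_sbp_pct(99.0)
        assert rr_i >= 0.01 and rr_s >= 0.01

    def test_power_mode_compounds(self):
        k = c.ConversionConstants(mode="power")
        rr_i, _ = c.rr_from_sbp_pct(2.0, k)
        assert rr_i == pytest.approx((1 - 0.034) ** 2, rel=1e-12)


class TestSodium:
    def test_zero_delta_is_zero_percent(self):
        assert c.sbp_pct_from_sodium(0.0, 60, "male") == 0.0

    def test_stated_formula_arithmetic(self):
        m = c.SodiumBPModel(slope_at_35=0.05, slope_age_gradient=0.0)
        pct = c.sbp_pct_from_sodium(10.0, 50, "male", m, baseline_sbp=125.0)
        assert pct == pytest.approx(100 * 0.05 * 10 / 125, rel=1e-12)  # 0.4%

    def test_sex_effect_ratio_tracks_sodium_ratio(self):
        m = c.SodiumBPModel(slope_at_35=0.05, slope_age_gradient=0.0)
        male = c.sbp_pct_from_sodium(10.6, 60, "male", m, 130.0)
        female = c.sbp_pct_from_sodium(7.3, 60, "female", m, 130.0)
        assert male / female == pytest.approx(10.6 / 7.3, rel=1e-12)

    def test_slope_nondecreasing_with_age(self):
        m = c.SodiumBPModel()
        slopes = [m.slope(a, "male") for a in range(35, 100, 5)]
        assert all(b >= a for a, b in zip(slopes, slopes[1:]))

    def test_mg_units_rescale(self):
        mmol = c.SodiumBPModel(units="mmol")
        mg = c.SodiumBPModel(units="mg")
        assert mg.slope(60, "male") == pytest.approx(
            mmol.slope(60, "male") / 23.0)


class TestCombineRRs:
    def test_statin_times_diuretic_worked_example(self):
        rr_i, _ = c.combine_rrs([(0.70, 0.81), (0.86, 0.62)])
        assert rr_i == pytest.approx(0.602, abs=1e-12)

    def test_single_effect_unchanged(self):
        assert c.combine_rrs([(0.9, 0.8)]) == (0.9, 0.8)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(
        st.floats(0.1, 2.0), st.floats(0.1, 2.0)), min_size=2, max_size=5),
        st.randoms(use_true_random=False))
    def test_commutative(self, effects, rnd):
        base = c.combine_rrs(effects)
        shuffled = list(effects)
        rnd.shuffle(shuffled)
        perm = c.combine_rrs(shuffled)
        assert perm[0] == pytest.approx(base[0], rel=1e-12)
        assert perm[1] == pytest.approx(base[1], rel=1e-12)

    def test_unit_rr_is_noop(self):
        assert c.combine_rrs([(1.0, 1.0), (0.7, 0.6)]) == \
            pytest.approx((0.7, 0.6))

    def test_nonpositive_rr_raises(self):
        with pytest.raises(c.DomainError):
            c.combine_rrs([(0.0, 0.5)])
        with pytest.raises(c.DomainError):
            c.combine_rrs([])


class TestAdherenceAndBlending:
    def test_adherent_fraction_defaults(self):
        a = c.AdherenceModel()
        assert a.adherent_fraction(1) == 1.0
        assert a.adherent_fraction(2) == pytest.approx(0.60)
        assert a.adherent_fraction(10) == pytest.approx(0.60)

    def test_full_coverage_year1_unchanged(self):
        rr = c.population_effective_rr(0.7, 1.0, c.AdherenceModel(), 1)
        assert rr == pytest.approx(0.7)

    def test_year2_blend_with_default_discontinuation(self):
        rr = c.population_effective_rr(0.7, 1.0, c.AdherenceModel(), 2)
        assert rr == pytest.approx(1 - 0.6 * (1 - 0.7))

    def test_zero_coverage_is_untreated(self):
        assert c.population_effective_rr(0.5, 0.0, c.AdherenceModel(), 3) \
            == pytest.approx(1.0)

    @settings(max_examples=60, derandomize=True)
    @given(st.floats(0.1, 1.9), st.floats(0, 1), st.floats(0, 1),
           st.integers(1, 20))
    def test_monotone_in_coverage(self, rr, cov_lo, cov_hi, year):
        lo, hi = sorted([cov_lo, cov_hi])
        a = c.AdherenceModel()
        e_lo = c.population_effective_rr(rr, lo, a, year)
        e_hi = c.population_effective_rr(rr, hi, a, year)
        if rr < 1:     # benefits: more coverage never raises effective RR
            assert e_hi <= e_lo + 1e-12
        else:          # harms scale the same way
            assert e_hi >= e_lo - 1e-12


class TestCosts:
    def test_diuretic_year1_full_coverage(self):
        iv = c.library_by_name()["Thiazide diuretic"]
        assert c.annual_cost(iv, 1, 1.0) == pytest.approx(71.0)

    def test_statin_nz_year3_scaled_by_adherence(self):
        nz = c.statin_nz_variant(c.library_by_name()["Statin"])
        assert c.annual_cost(nz, 3, 1.0) == pytest.approx(19.0 * 0.6)

    def test_zero_coverage_costs_nothing(self):
        iv = c.library_by_name()["Statin"]
        assert c.annual_cost(iv, 1, 0.0) == 0.0

    def test_unknown_perspective_raises(self):
        iv = c.library_by_name()["Statin"]
        with pytest.raises(c.DomainError):
            c.annual_cost(iv, 1, 1.0, perspective="societal")

    def test_cost_split_sums_to_total(self):
        for iv in c.builtin_intervention_library():
            for year in (1, 2):
                total = iv.costs.split(year, "both")
                parts = (iv.costs.split(year, "government")
                         + iv.costs.split(year, "patient"))
                assert total == pytest.approx(parts)


class TestSampleDraw:
    def _zero_se(self, iv):
        unc = {k: replace(u, se=0.0) for k, u in iv.uncertainty.items()}
        return replace(iv, uncertainty=unc)

    def test_zero_se_draw_equals_mean(self):
        rng = np.random.default_rng(0)
        for iv in c.builtin_intervention_library():
            drawn = c.sample_draw(self._zero_se(iv), rng)
            assert drawn.effect == iv.effect, iv.name
            assert drawn.costs == iv.costs, iv.name

    def test_moment_matching_of_lognormal_rr(self):
        iv = c.library_by_name()["Thiazide diuretic"]
        rng = np.random.default_rng(42)
        draws = np.array([c.sample_draw(iv, rng).effect.rr_ihd
                          for _ in range(10_000)])
        se = 0.06 / math.sqrt(len(draws))
        assert abs(draws.mean() - 0.86) < 3 * se
        assert draws.std() == pytest.approx(0.06, rel=0.05)
        assert (draws > 0).all()

    def test_same_rng_state_gives_identical_draws(self):
        iv = c.library_by_name()["Aspirin"]
        a = c.sample_draw(iv, np.random.default_rng(9))
        b = c.sample_draw(iv, np.random.default_rng(9))
        assert a == b

    def test_negative_se_rejected(self):
        with pytest.raises(c.ConfigurationError):
            ParamUncertainty(mean=1.0, se=-0.1).validate("x")

    def test_cost_draws_preserve_split_shares(self):
        iv = c.library_by_name()["Lifestyle program"]
        rng = np.random.default_rng(3)
        drawn = c.sample_draw(iv, rng)
        assert drawn.costs.year1_gov >= 0
        # all-government intervention stays all-government
        assert drawn.costs.year1_patient == 0.0
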