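"""Generalized CEA: null back-calculation, evaluation, expansion path,
PSA and the acceptability frontier."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import cvdcea as c
from cvdcea.cea import Candidate, ExpansionPath, ExpansionStep


def popwide_rr_intervention(rr, name="uniform", cost=0.0):
    return c.Intervention(
        name=name, delivery="population_wide",
        effect=c.EffectSpec(rr_ihd=rr, rr_stroke=rr, rr_gi_bleed=rr),
        costs=c.CostSchedule(year1_gov=cost), adherence=c.FULL_ADHERENCE)


class TestBackCalculation:
    def test_zero_coverage_null_equals_observed(self, ctx):
        empty = c.Scenario(label="nothing")
        null = c.backcalculate_null(ctx, current_practice=empty)
        pd.testing.assert_frame_equal(null.frame, ctx.epi_observed.frame)

    def test_uniform_rr_scales_incidence(self, ctx):
        sc = c.Scenario(label="uniform", entries=(
            c.ScenarioEntry(popwide_rr_intervention(0.9)),))
        null = c.backcalculate_null(ctx, current_practice=sc)
        assert null.frame["ihd_incidence"].to_numpy() == pytest.approx(
            ctx.epi_observed.frame["ihd_incidence"].to_numpy() / 0.9,
            rel=1e-12)

    def test_round_trip_recovers_observed(self, ctx):
        avg = c.population_average_rr(ctx, ctx.current_practice)
        recovered = c.apply_practice(ctx.epi_null, avg)
        for col in ("ihd_incidence", "stroke_incidence",
                    "gi_bleed_incidence"):
            err = np.abs(recovered.frame[col].to_numpy()
                         - ctx.epi_observed.frame[col].to_numpy())
            assert err.max() < 1e-9

    def test_average_rr_below_one_under_current_practice(self, ctx):
        avg = c.population_average_rr(ctx, ctx.current_practice)
        assert (avg["ihd"] < 1.0).all()
        assert (avg["ihd"] > 0.0).all()


class TestEvaluateVsNull:
    def test_do_nothing_scores_zero(self, ctx, null_totals):
        o = c.evaluate_vs_null(ctx, c.DO_NOTHING, null_totals=null_totals)
        assert o.health_gain == 0.0
        assert o.net_cost == 0.0

    def test_pure_cost_intervention_is_dominated(self, ctx, null_totals):
        iv = popwide_rr_intervention(1.0, name="placebo", cost=10.0)
        o = c.evaluate_vs_null(
            ctx, c.Scenario(label="placebo",
                            entries=(c.ScenarioEntry(iv),)),
            null_totals=null_totals)
        assert o.health_gain == pytest.approx(0.0, abs=1e-6)
        assert o.cost_gov > 0
        assert o.classification == "dominated"

    def test_hand_computed_toy_icer(self):
        """Single cohort, no disease, flat mortality, fixed per-person
        cost, benefit only through a fabricated stroke-risk channel set
        to zero: ICER equals hand-summed cost / hand-summed gain."""
        from conftest import make_epi, make_weights
        epi = make_epi(ihd=0.01, background_mortality=0.02, ihd_cf=0.0)
        weights = make_weights(ihd=0.2)
        cost_table = c.DiseaseCostTable(
            first_year={"ihd": 1000.0, "stroke": 0, "gi_bleed": 0},
            subsequent_year={"ihd": 100.0, "stroke": 0, "gi_bleed": 0})
        cfg = c.MarkovConfig(excess_mortality_ihd=0.0,
                             excess_mortality_stroke=0.0, age_cap=41.0)
        d = c.DiscountSpec(rate=0.0)
        base = c.simulate_cohort(100.0, 37.5, "male", epi, weights,
                                 cost_table, config=cfg)
        treated = c.simulate_cohort(
            100.0, 37.5, "male", epi, weights, cost_table,
            rr_schedule=lambda y: (0.5, 1.0, 1.0),
            intervention_cost=lambda y, alive_frac: (40.0 * alive_frac, 0.0),
            config=cfg)
        gain = (c.discounted_sum(treated.haly_daly, d)
                - c.discounted_sum(base.haly_daly, d))
        net = (c.discounted_sum(treated.cost_gov, d)
               + c.discounted_sum(treated.disease_cost, d)
               - c.discounted_sum(base.disease_cost, d))
        # independent hand recomputation from first principles
        def hand(rr):
            occ_w, occ_i, lys, halys, dis, prog = 100.0, 0.0, [], [], [], []
            for t in range(4):   # age cap 41 - entry 37.5 -> 4 cycles
                lam, m = 0.01 * rr, 0.02
                tot = lam + m
                p_exit = -math.expm1(-tot)
                p_i = lam / tot * p_exit
                p_m = m / tot * p_exit
                e_i = occ_w * p_i
                alive = occ_w + occ_i
                lys.append(alive)
                halys.append(occ_w + occ_i * 0.8)
                dis.append(e_i * 1000.0 + occ_i * 100.0)
                # program cost: $40 per unit of alive fraction, as wired
                prog.append(40.0 * alive / 100.0 if rr < 1 else 0.0)
                die_i = occ_i * -math.expm1(-m)
                occ_w, occ_i = occ_w - e_i - occ_w * p_m, \
                    occ_i - die_i + e_i
            return (sum(halys), sum(dis), sum(prog))
        h_base = hand(1.0)
        h_tr = hand(0.5)
        hand_gain = h_tr[0] - h_base[0]
        hand_net = h_tr[2] + h_tr[1] - h_base[1]
        assert gain == pytest.approx(hand_gain, rel=1e-12)
        assert net == pytest.approx(hand_net, rel=1e-12)
        assert net / gain == pytest.approx(hand_net / hand_gain, rel=1e-12)

    def test_salt_is_cost_saving_dominant(self, ctx, null_totals):
        salt = ctx.library["Mandatory salt reduction"]
        o = c.evaluate_vs_null(
            ctx, c.Scenario(label="salt", entries=(c.ScenarioEntry(salt),)),
            null_totals=null_totals)
        assert o.classification == "dominant"
        assert o.icer_display() == "Dominant"


@pytest.fixture(scope="module")
def small_candidates(ctx):
    lib = ctx.library
    return [
        Candidate(lib["Mandatory salt reduction"]),
        Candidate(lib["Thiazide diuretic"], ">=15%"),
        Candidate(lib["Calcium channel blocker"], ">=15%"),
        Candidate(lib["Statin"], ">=15%"),
        Candidate(replace(lib["Lifestyle program"],
                          effectiveness_scale=0.01), ">=15%"),
    ]


@pytest.fixture(scope="module")
def small_path(ctx, small_candidates):
    return c.expansion_path(ctx, small_candidates)


class TestExpansionPath:
    def test_single_candidate_path_equals_vs_null(self, ctx):
        cand = Candidate(ctx.library["Thiazide diuretic"], ">=15%")
        path = c.expansion_path(ctx, [cand])
        assert len(path.steps) == 1
        o = c.evaluate_vs_null(
            ctx, c.Scenario(label="d", entries=(cand.entry(),)))
        assert path.steps[0].inc_gain == pytest.approx(o.health_gain,
                                                       rel=1e-9)
        assert path.steps[0].inc_net == pytest.approx(o.net_cost, rel=1e-9)

    def test_duplicate_target_population_shrinks_increment(self, ctx):
        lib = ctx.library
        twin = replace(lib["Thiazide diuretic"], name="Thiazide duplicate")
        cands = [Candidate(lib["Thiazide diuretic"], ">=15%"),
                 Candidate(twin, ">=15%")]
        path = c.expansion_path(ctx, cands, exclusivity={})
        standalone = c.evaluate_vs_null(
            ctx, c.Scenario(label="t", entries=(cands[1].entry(),)))
        assert len(path.steps) == 2
        assert path.steps[1].inc_gain < standalone.health_gain

    def test_cumulative_gain_nondecreasing(self, small_path):
        gains = [s.cum_gain for s in small_path.steps]
        assert all(b >= a for a, b in zip(gains, gains[1:]))

    def test_incremental_icers_nondecreasing(self, small_path):
        icers = [s.inc_icer for s in small_path.steps
                 if not s.dominant and s.inc_icer is not None]
        assert all(b >= a - 1e-9 for a, b in zip(icers, icers[1:]))

    def test_threshold_cut_bookkeeping(self):
        steps = [
            ExpansionStep("a", "all", 10, -5.0, None, True, 10, -5.0),
            ExpansionStep("b", "all", 10, 2e5, 20_000.0, False, 20, 2e5),
            ExpansionStep("c", "all", 10, 6e5, 60_000.0, False, 30, 8e5),
        ]
        path = ExpansionPath(steps=steps, package=c.DO_NOTHING,
                             skipped=[], threshold=50_000.0)
        assert path.threshold_cut == 2
        assert [s.name for s in path.package_under_threshold()] == ["a", "b"]

    def test_reordering_candidates_does_not_change_path(self, ctx,
                                                        small_candidates):
        a = c.expansion_path(ctx, small_candidates)
        b = c.expansion_path(ctx, list(reversed(small_candidates)))
        assert [(s.name, s.band) for s in a.steps] == \
            [(s.name, s.band) for s in b.steps]

    def test_exclusivity_skips_beta_blocker(self, ctx):
        lib = ctx.library
        cands = [Candidate(lib["Thiazide diuretic"], ">=15%"),
                 Candidate(lib["Beta-blocker"], ">=15%")]
        path = c.expansion_path(ctx, cands)
        names = {s.name for s in path.steps}
        assert "Beta-blocker" not in names
        assert ("Beta-blocker", ">=15%",
                "more cost-effective alternative available") in path.skipped


class TestPSA:
    def _zero_se_library(self, ctx):
        out = {}
        for name, iv in ctx.library.items():
            unc = {k: replace(u, se=0.0) for k, u in iv.uncertainty.items()}
            out[name] = replace(iv, uncertainty=unc)
        return out

    def test_zero_se_draws_identical_and_match_deterministic(self, ctx):
        lib0 = self._zero_se_library(ctx)
        salt = lib0["Mandatory salt reduction"]
        sc = c.Scenario(label="salt", entries=(c.ScenarioEntry(salt),))
        ctx2 = replace_library(ctx, lib0)
        psa = c.run_psa(ctx2, {"salt": sc}, n_draws=5, seed=11)
        gain, net = psa.gain_net("salt")
        assert np.ptp(gain) == 0.0 and np.ptp(net) == 0.0
        det = c.evaluate_vs_null(ctx2, sc)
        assert gain[0] == pytest.approx(det.health_gain, rel=1e-12)
        assert net[0] == pytest.approx(det.net_cost, rel=1e-12)
        s = psa.summary("salt")
        assert s["health_gain"]["lo95"] == s["health_gain"]["hi95"]

    def test_same_seed_identical_summaries(self, ctx):
        sc = c.Scenario(label="salt", entries=(
            c.ScenarioEntry(ctx.library["Mandatory salt reduction"]),))
        a = c.run_psa(ctx, {"salt": sc}, n_draws=8, seed=5)
        b = c.run_psa(ctx, {"salt": sc}, n_draws=8, seed=5)
        for (ga, na), (gb, nb) in [(a.gain_net("salt"), b.gain_net("salt"))]:
            assert np.array_equal(ga, gb) and np.array_equal(na, nb)

    def test_n_draws_below_two_rejected(self, ctx):
        with pytest.raises(c.ConfigurationError):
            c.run_psa(ctx, {}, n_draws=1, seed=0)

    def test_generic_engine_analytic_icer_quantiles(self):
        """ICER = cost / gain with gain ~ N(100, 10) and fixed cost:
        empirical 95% UI at 10,000 draws matches the analytic quantiles
        of the ratio within Monte Carlo error."""
        cost = 5_000.0
        mu, sigma = 100.0, 10.0
        draws = c.psa_engine(
            sample_fn=lambda rng: rng.normal(mu, sigma),
            evaluate_fn=lambda g: {"gain": g, "net": cost},
            n_draws=10_000, seed=17)
        lo, med, hi = c.icer_quantiles(draws["gain"].to_numpy(),
                                       draws["net"].to_numpy())
        z = 1.959963984540054
        analytic_lo = cost / (mu + z * sigma)
        analytic_hi = cost / (mu - z * sigma)
        analytic_med = cost / mu
        assert lo == pytest.approx(analytic_lo, rel=0.02)
        assert med == pytest.approx(analytic_med, rel=0.02)
        assert hi == pytest.approx(analytic_hi, rel=0.02)


def replace_library(ctx, new_lib):
    import copy
    ctx2 = copy.copy(ctx)
    ctx2.library = new_lib
    ctx2._cache = {}
    return ctx2


class TestAcceptabilityFrontier:
    def test_single_package_probability_one(self):
        rng = np.random.default_rng(0)
        draws = {"only": (rng.normal(10, 1, 500), rng.normal(5, 1, 500))}
        f = c.acceptability_frontier(draws, thresholds=[0, 1000, 50_000])
        assert (f["only"] == 1.0).all()
        assert (f["frontier_probability"] == 1.0).all()

    def test_lambda_zero_lowest_net_cost_wins(self):
        n = 400
        rng = np.random.default_rng(1)
        cheap = (rng.normal(1, 0.1, n), rng.normal(10.0, 0.1, n))
        dear = (rng.normal(50, 0.1, n), rng.normal(1000.0, 0.1, n))
        f = c.acceptability_frontier({"cheap": cheap, "dear": dear},
                                     thresholds=[0.0])
        assert f.loc[0.0, "cheap"] == 1.0

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(2)
        n = 300
        draws = {k: (rng.normal(10 * (i + 1), 3, n),
                     rng.normal(1000 * (i + 1) ** 2, 300, n))
                 for i, k in enumerate("abc")}
        f = c.acceptability_frontier(draws,
                                     thresholds=np.arange(0, 5000, 250.0))
        sums = f[list("abc")].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_two_package_crossing_matches_closed_form(self):
        """With degenerate (zero-variance) draws the frontier switches
        exactly at lambda* = (net2-net1)/(gain2-gain1)."""
        n = 50
        a = (np.full(n, 10.0), np.full(n, 100.0))
        b = (np.full(n, 20.0), np.full(n, 600.0))
        lam_star = (600.0 - 100.0) / (20.0 - 10.0)   # 50
        grid = np.arange(0.0, 101.0, 1.0)
        f = c.acceptability_frontier({"a": a, "b": b}, thresholds=grid)
        assert (f.loc[f.index < lam_star, "a"] == 1.0).all()
        assert (f.loc[f.index > lam_star, "b"] == 1.0).all()

    def test_misaligned_draws_rejected(self):
        with pytest.raises(c.DataError):
            c.acceptability_frontier(
                {"a": (np.ones(5), np.ones(5)),
                 "b": (np.ones(4), np.ones(4))}, thresholds=[0.0])


class TestPackageLedger:
    def test_zero_effect_package_all_zero(self, ctx):
        sc = c.Scenario(label="nothing-much", entries=())
        frame = c.package_ledger(ctx, sc)
        assert np.allclose(frame["value"].to_numpy(), 0.0)

    def test_net_cost_accounting_identity(self, ctx):
        sc = c.Scenario(label="salt", entries=(
            c.ScenarioEntry(ctx.library["Mandatory salt reduction"]),))
        frame = c.package_ledger(ctx, sc)
        v = frame["value"]
        assert v["net_lifetime_cost"] == pytest.approx(
            v["intervention_cost_government"]
            + v["intervention_cost_patients"]
            + v["treatment_costs_averted"], rel=1e-12)

    def test_nz_statin_price_cuts_gov_cost_not_health(self, ctx):
        lib = ctx.library
        aus = c.Scenario(label="aus", entries=(
            c.ScenarioEntry(lib["Statin"], bands=(">=15%",)),))
        nz = c.Scenario(label="nz", entries=(
            c.ScenarioEntry(c.statin_nz_variant(lib["Statin"]),
                            bands=(">=15%",)),))
        o_aus = c.evaluate_vs_null(ctx, aus)
        o_nz = c.evaluate_vs_null(ctx, nz)
        assert o_nz.cost_gov < o_aus.cost_gov
        assert o_nz.health_gain == pytest.approx(o_aus.health_gain,
                                                 rel=1e-12)
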