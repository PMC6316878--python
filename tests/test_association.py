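
import numpy as np
import pytest
from scipy import stats

from pharmprio import association as assoc
from pharmprio import synthetic_cohort

from oracles import (
    exact_permutation_response_p,
    km_brute_force,
    logrank_brute_force,
)


class TestResponseChisq:
    def test_published_3x2_table_p_0003(self):
        r = assoc.response_chisq([[42, 9], [66, 17], [19, 17]])
        assert r.df == 2
        assert round(r.p_value, 3) == 0.003

    def test_published_3x2_table_p_below_0001(self):
        r = assoc.response_chisq([[88, 16], [29, 24], [9, 2]])
        assert r.p_value < 0.001

    def test_identical_row_proportions(self):
        r = assoc.response_chisq([[10, 20], [20, 40], [5, 10]])
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_matches_scipy_uncorrected(self, rng):
        for _ in range(50):
            table = rng.integers(1, 30, size=(3, 2))
            mine = assoc.response_chisq(table)
            ref = stats.chi2_contingency(table, correction=False)
            assert mine.statistic == pytest.approx(ref[0])
            assert mine.p_value == pytest.approx(ref[1])

    def test_zero_margin_raises(self):
        with pytest.raises(assoc.DegenerateTableError):
            assoc.response_chisq([[0, 0], [3, 4]])


class TestTruncateDfs:
    def test_above_horizon_censored(self):
        t, e = assoc.truncate_dfs([130.0], [True])
        assert t[0] == 120.0 and not e[0]

    def test_boundary_unchanged(self):
        t, e = assoc.truncate_dfs([120.0], [True])
        assert t[0] == 120.0 and e[0]

    def test_below_horizon_unchanged(self):
        t, e = assoc.truncate_dfs([60.0], [False])
        assert t[0] == 60.0 and not e[0]

    def test_negative_time_raises(self):
        with pytest.raises(ValueError):
            assoc.truncate_dfs([-1.0], [True])


class TestKaplanMeier:
    def test_no_censoring_empirical_survival(self):
        c = assoc.km_estimate([1, 2, 3, 4], [True] * 4)
        assert c.survival == pytest.approx([0.75, 0.5, 0.25, 0.0])

    def test_all_censored_flat_one(self):
        c = assoc.km_estimate([5, 8, 2], [False] * 3)
        assert c.event_times.size == 0
        assert c.survival_at(100.0) == 1.0

    def test_hand_product_limit_with_censoring(self):
        # events at 1 and 3, censored at 2: S(3) = (3/4)*(1/2) = 0.375
        c = assoc.km_estimate([1, 2, 3, 4], [True, False, True, False])
        assert c.survival_at(3.0) == pytest.approx(0.375)

    def test_brute_force_risk_set_recomputation(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 9))
            times = rng.integers(1, 6, size=n).astype(float)
            events = rng.random(n) < 0.7
            c = assoc.km_estimate(times, events)
            t_ref, s_ref = km_brute_force(times, events)
            assert c.event_times == pytest.approx(t_ref)
            assert c.survival == pytest.approx(s_ref)

    def test_monotone_within_unit_interval(self, rng):
        times = rng.exponential(50, size=40)
        events = rng.random(40) < 0.6
        c = assoc.km_estimate(times, events)
        assert ((c.survival >= -1e-12) & (c.survival <= 1 + 1e-12)).all()
        assert (np.diff(c.survival) <= 1e-12).all()

    def test_rmst_hand_computation(self):
        # steps: S=1 on [0,1), 0.75 on [1,3), 0.375 on [3,10)
        c = assoc.km_estimate([1, 2, 3, 4], [True, False, True, False])
        expected = 1.0 * 1 + 0.75 * 2 + 0.375 * 7
        assert c.rmst(10.0) == pytest.approx(expected)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            assoc.km_estimate([], [])

    def test_km_curve_table_export(self):
        curves = {
            0: assoc.km_estimate([1, 2, 3, 4], [True, False, True, False]),
            1: assoc.km_estimate([5.0], [True]),
        }
        table = assoc.km_curve_table(curves)
        assert list(table.columns) == ["group", "time", "survival", "at_risk", "n_events"]
        g0 = table[table["group"] == 0]
        assert g0["time"].tolist() == [0.0, 1.0, 3.0]
        assert g0["survival"].tolist() == pytest.approx([1.0, 0.75, 0.375])
        assert (table.groupby("group")["survival"].apply(lambda s: (s.diff().dropna() <= 0).all())).all()


class TestLogrank:
    def test_identical_groups_null(self):
        g = (np.array([1.0, 2, 3, 4]), np.array([True, True, False, True]))
        r = assoc.logrank([g, g])
        assert r.statistic == pytest.approx(0.0, abs=1e-9)
        assert r.p_value == pytest.approx(1.0)

    def test_hand_computed_two_group_example(self):
        # group A: events at 1, 2; group B: event at 3, censored at 4
        a = (np.array([1.0, 2.0]), np.array([True, True]))
        b = (np.array([3.0, 4.0]), np.array([True, False]))
        # t=1: O_A=1 E_A=2/4 V=(1*3/3)*(2/4)(1-2/4)=0.25
        # t=2: O_A=1 E_A=1/3 V=(1*2/2)*(1/3)(2/3)=2/9
        # t=3: O_A=0 E_A=0   V=0
        oe = (1 - 0.5) + (1 - 1 / 3)
        v = 0.25 + 2 / 9
        expected = oe**2 / v
        r = assoc.logrank([a, b])
        assert r.statistic == pytest.approx(expected)

    def test_three_groups_df_two(self, rng):
        groups = [
            (rng.exponential(10, 20), rng.random(20) < 0.8) for _ in range(3)
        ]
        assert assoc.logrank(groups).df == 2

    def test_all_censored_flagged(self):
        g1 = (np.array([1.0, 2.0]), np.array([False, False]))
        g2 = (np.array([3.0, 4.0]), np.array([False, False]))
        r = assoc.logrank([g1, g2])
        assert r.flagged and r.p_value == 1.0

    def test_brute_force_small_n(self, rng):
        for _ in range(60):
            sizes = rng.integers(2, 5, size=2)
            groups = [
                (rng.integers(1, 6, size=s).astype(float), rng.random(s) < 0.7)
                for s in sizes
            ]
            if not any(e.any() for _, e in groups):
                continue
            mine = assoc.logrank(groups)
            stat_ref, p_ref = logrank_brute_force(groups)
            assert mine.statistic == pytest.approx(stat_ref, abs=1e-9)
            assert mine.p_value == pytest.approx(p_ref, abs=1e-9)

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import multivariate_logrank_test

        times = rng.exponential(20, size=90)
        events = rng.random(90) < 0.7
        groups = rng.integers(0, 3, size=90)
        mine = assoc.logrank(
            [(times[groups == g], events[groups == g]) for g in range(3)]
        )
        ref = multivariate_logrank_test(times, groups, events)
        assert mine.statistic == pytest.approx(ref.test_statistic)
        assert mine.p_value == pytest.approx(ref.p_value)


class TestPermAdjust:
    def test_constant_outcome_flagged(self):
        r = assoc.perm_adjust(
            "response", np.ones(10, dtype=int), np.repeat([0, 1], 5), seed=0
        )
        assert r.flagged and r.adjusted_p == 1.0

    def test_exact_enumeration_n7(self):
        outcome = np.array([1, 1, 1, 0, 0, 0, 1])
        groups = np.array([0, 0, 0, 1, 1, 1, 1])
        p_obs, exact_ref = exact_permutation_response_p(outcome, groups)
        r = assoc.perm_adjust("response", outcome, groups, exact=True)
        assert r.exact
        assert r.raw_p == pytest.approx(p_obs)
        assert r.adjusted_p == pytest.approx(exact_ref)

    def test_exact_enumeration_stratified(self):
        outcome = np.array([1, 0, 1, 0, 1, 0])
        groups = np.array([0, 1, 0, 1, 0, 1])
        strata = np.array([0, 0, 0, 1, 1, 1])
        r = assoc.perm_adjust("response", outcome, groups, strata=strata, exact=True)
        assert r.n_permutations == 36  # 3! * 3!
        assert 0.0 < r.adjusted_p <= 1.0

    def test_monte_carlo_converges_to_exact(self):
        outcome = np.array([1, 1, 1, 0, 0, 0, 1])
        groups = np.array([0, 0, 0, 1, 1, 1, 1])
        _, exact_ref = exact_permutation_response_p(outcome, groups)
        r = assoc.perm_adjust("response", outcome, groups, n_permutations=20000, seed=5)
        se = np.sqrt(exact_ref * (1 - exact_ref) / 20000)
        assert abs(r.adjusted_p - exact_ref) < 4 * se + 1e-4

    def test_adjusted_p_on_add_one_grid(self, rng):
        outcome = (rng.random(30) < 0.5).astype(int)
        groups = rng.integers(0, 2, size=30)
        b = 37
        r = assoc.perm_adjust("response", outcome, groups, n_permutations=b, seed=1)
        k = round(r.adjusted_p * (b + 1))
        assert r.adjusted_p == pytest.approx(k / (b + 1))
        assert 1 <= k <= b + 1

    def test_seed_reproducible(self, rng):
        outcome = (rng.random(40) < 0.5).astype(int)
        groups = rng.integers(0, 3, size=40)
        r1 = assoc.perm_adjust("response", outcome, groups, n_permutations=100, seed=9)
        r2 = assoc.perm_adjust("response", outcome, groups, n_permutations=100, seed=9)
        assert r1.adjusted_p == r2.adjusted_p

    def test_dfs_mode_runs(self, rng):
        t = rng.exponential(30, 40)
        e = rng.random(40) < 0.7
        groups = rng.integers(0, 2, size=40)
        r = assoc.perm_adjust("dfs", (t, e), groups, n_permutations=50, seed=3)
        assert 0 < r.adjusted_p <= 1.0
        assert r.n_permutations == 50

    def test_default_permutation_counts(self, rng):
        outcome = (rng.random(20) < 0.5).astype(int)
        groups = rng.integers(0, 2, size=20)
        assert (
            assoc.perm_adjust("response", outcome, groups, seed=0).n_permutations
            == 1000
        )
        t = rng.exponential(30, 20)
        e = rng.random(20) < 0.8
        assert assoc.perm_adjust("dfs", (t, e), groups, seed=0).n_permutations == 100


def _breslow_loglik(beta, times, events, x):
    """Independent Cox partial log-likelihood (no ties in the data used)."""
    ll = 0.0
    for i in range(len(times)):
        if not events[i]:
            continue
        risk = times >= times[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


class TestCoxFit:
    def test_score_test_identity_with_logrank(self, rng):
        # With untied data, U(0)^2 / I(0) equals the two-group log-rank stat.
        n = 40
        times = rng.exponential(20, n) + rng.random(n) * 1e-6
        events = rng.random(n) < 0.7
        x = rng.integers(0, 2, size=n).astype(float)
        h = 1e-5
        u = (_breslow_loglik(h, times, events, x) - _breslow_loglik(-h, times, events, x)) / (2 * h)
        info = -(
            _breslow_loglik(h, times, events, x)
            - 2 * _breslow_loglik(0.0, times, events, x)
            + _breslow_loglik(-h, times, events, x)
        ) / h**2
        score_stat = u**2 / info
        lr = assoc.logrank([(times[x == 0], events[x == 0]), (times[x == 1], events[x == 1])])
        assert score_stat == pytest.approx(lr.statistic, rel=1e-3)

    def test_planted_hr_recovered(self):
        cfg = synthetic_cohort.SimulationConfig(
            n_samples=400, n_variants=1, maf=0.3, seed=42,
            effects={"var00000": synthetic_cohort.VariantEffect(dfs_hr=2.5)},
            baseline_hazard=0.02, censoring_rate=0.005,
        )
        g = synthetic_cohort.gen_genotypes(cfg)
        t, e = synthetic_cohort.gen_survival(g, cfg)
        fit = assoc.cox_fit(t, e, g.row("var00000").astype(float))
        assert fit.ci_low < 2.5 < fit.ci_high
        assert fit.lrt_p < 0.01

    def test_no_events_flagged(self):
        fit = assoc.cox_fit([1.0, 2.0, 3.0], [False] * 3, [0.0, 1.0, 2.0])
        assert fit.flagged

    def test_hr_is_exp_coef(self, rng):
        t = rng.exponential(10, 100)
        e = rng.random(100) < 0.8
        x = rng.integers(0, 3, 100).astype(float)
        fit = assoc.cox_fit(t, e, x)
        assert fit.ratio == pytest.approx(np.exp(fit.coef))
        assert fit.ci_low < fit.ratio < fit.ci_high

    def test_null_lrt_p_roughly_uniform(self):
        ps = []
        for seed in range(40):
            r = np.random.default_rng(seed)
            t = r.exponential(10, 80)
            e = r.random(80) < 0.8
            x = r.integers(0, 3, 80).astype(float)
            ps.append(assoc.cox_fit(t, e, x).lrt_p)
        assert stats.kstest(ps, "uniform").pvalue > 0.001


class TestLogisticFit:
    def test_lrt_agrees_with_pearson_on_2x2(self):
        # 2x2 with comfortable expected counts
        y = np.array([1] * 30 + [0] * 20 + [1] * 15 + [0] * 35)
        x = np.array([0.0] * 50 + [1.0] * 50)
        fit = assoc.logistic_fit(y, x)
        pearson = assoc.response_chisq([[30, 20], [15, 35]])
        assert fit.lrt_p == pytest.approx(pearson.p_value, rel=0.2)

    def test_separation_flagged(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        x = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        fit = assoc.logistic_fit(y, x)
        assert fit.flagged

    def test_planted_or_recovered(self):
        cfg = synthetic_cohort.SimulationConfig(
            n_samples=2000, n_variants=1, maf=0.3, seed=11,
            effects={"var00000": synthetic_cohort.VariantEffect(response_or=3.0)},
            baseline_response_rate=0.3,
        )
        g = synthetic_cohort.gen_genotypes(cfg)
        y = synthetic_cohort.gen_response(g, cfg).astype(int)
        fit = assoc.logistic_fit(y, g.row("var00000").astype(float))
        assert fit.ci_low < 3.0 < fit.ci_high
        assert fit.lrt_p < 1e-4


class TestPAdjust:
    P5 = [0.01, 0.04, 0.03, 0.005, 0.2]
    # frozen from R stats::p.adjust on P5
    EXPECTED = {
        "bonferroni": [0.05, 0.2, 0.15, 0.025, 1.0],
        "holm": [0.04, 0.09, 0.09, 0.025, 0.2],
        "hochberg": [0.04, 0.08, 0.08, 0.025, 0.2],
        "hommel": [0.04, 0.08, 0.06, 0.025, 0.2],
        "fdr_bh": [0.025, 0.05, 0.05, 0.025, 0.2],
    }

    @pytest.mark.parametrize("method", sorted(EXPECTED))
    def test_matches_hand_stepped_reference(self, method):
        assert assoc.p_adjust(self.P5, method) == pytest.approx(self.EXPECTED[method])

    def test_single_p_unchanged(self):
        for method in self.EXPECTED:
            assert assoc.p_adjust([0.03], method) == pytest.approx([0.03])

    def test_bonferroni_simple(self):
        assert assoc.p_adjust([0.01, 0.04], "bonferroni") == pytest.approx([0.02, 0.08])

    def test_ordering_property(self, rng):
        p = rng.random(20)
        bonf = assoc.p_adjust(p, "bonferroni")
        holm = assoc.p_adjust(p, "holm")
        assert (bonf >= holm - 1e-12).all()
        assert (holm >= p - 1e-12).all()
        for method in self.EXPECTED:
            assert (assoc.p_adjust(p, method) <= 1.0 + 1e-12).all()

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            assoc.p_adjust([1.5], "holm")
        with pytest.raises(ValueError):
            assoc.p_adjust([0.5], "banana")
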