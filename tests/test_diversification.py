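"""Likelihoods, ML fits, AIC/LRT arithmetic, LTT analysis."""

import numpy as np
import pytest
from scipy.special import gammaln

import chronodiv as cd
from chronodiv.errors import DomainError, InsufficientTipsError


def closed_form_constant_loglik(tree, lam):
    """Independent closed form: (n-2) ln λ - λ X + ln((n-1)!)."""
    X = tree.total_branch_length()
    return (tree.n - 2) * np.log(lam) - lam * X + float(gammaln(tree.n))


class TestIntegratedIntensity:
    def test_constant_is_lambda_times_X(self, toy_tree):
        assert cd.integrated_intensity(cd.ConstantRate(0.2), toy_tree) == pytest.approx(
            0.2 * 5.0
        )

    def test_piecewise_toy(self, toy_tree):
        # epoch lineage-times are 2 (ages 2-1) and 3 (ages 1-0)
        m = cd.PiecewiseRate((0.1, 0.3), (1.0,))
        assert cd.integrated_intensity(m, toy_tree) == pytest.approx(1.1)

    @pytest.mark.parametrize("a,b", [(-0.028, -1.607), (0.0, -2.0), (0.05, -3.0)])
    def test_logistic_matches_quadrature_oracle(self, a, b):
        from scipy.integrate import quad

        tree = cd.simulate_yule_tree(cd.ConstantRate(0.1), duration=30, seed=11)
        m = cd.LogisticRate(a, b)
        ts = np.sort(tree.root_age - tree.event_ages)
        knots = np.concatenate((ts, [tree.root_age]))
        oracle = 0.0
        for i in range(len(knots) - 1):
            q, _ = quad(
                lambda t: (i + 2) * m.rate_at(t, tree.root_age), knots[i], knots[i + 1]
            )
            oracle += q
        assert cd.integrated_intensity(m, tree) == pytest.approx(oracle, abs=1e-6)


class TestYuleTimeLoglik:
    def test_toy_constant_value(self, toy_tree):
        ll = cd.yule_time_loglik(cd.ConstantRate(0.2), toy_tree)
        assert ll == pytest.approx(np.log(0.2) - 1.0 + np.log(2.0), abs=1e-9)
        assert ll == pytest.approx(-1.9163, abs=5e-5)

    def test_constant_matches_closed_form_on_random_trees(self, random_trees):
        rng = np.random.default_rng(7)
        assert len(random_trees) >= 90
        for tree in random_trees:
            lam = float(rng.uniform(0.02, 0.5))
            got = cd.yule_time_loglik(cd.ConstantRate(lam), tree)
            assert got == pytest.approx(
                closed_form_constant_loglik(tree, lam), rel=1e-9, abs=1e-9
            )

    def test_mle_maximizes(self, toy_tree):
        at = lambda lam: cd.yule_time_loglik(cd.ConstantRate(lam), toy_tree)
        assert at(0.2) > at(0.1)
        assert at(0.2) > at(0.3)

    def test_zero_rate_epoch_with_event_gives_minus_inf(self, toy_tree):
        m = cd.PiecewiseRate((0.2, 0.0), (1.5,))  # event at age 1 in zero epoch
        assert cd.yule_time_loglik(m, toy_tree) == -np.inf

    def test_insufficient_tips(self):
        cherry = cd.read_newick("(A:1,B:1);")
        with pytest.raises(InsufficientTipsError):
            cd.yule_time_loglik(cd.ConstantRate(0.1), cherry)


class TestFitYuleConstant:
    def test_toy_closed_form(self, toy_tree):
        fit = cd.fit_yule_constant(toy_tree)
        assert fit.params["lambda"] == pytest.approx(0.2)
        assert fit.llf == pytest.approx(-1.9163, abs=5e-5)
        assert fit.k == 1
        assert fit.aic == pytest.approx(-2 * fit.llf + 2)
        assert fit.bse["lambda"] == pytest.approx(0.2)  # λ̂/sqrt(n-2), n=3

    def test_results_summary_mentions_estimates(self, toy_tree):
        s = cd.fit_yule_constant(toy_tree).summary()
        assert "lambda" in s and "AIC" in s


class TestFitYulePiecewise:
    def test_toy_fixed_breakpoint(self, toy_tree):
        fit = cd.fit_yule_piecewise(toy_tree, 2, fixed_breakpoints=[1.0])
        # boundary event at age 1 belongs to the younger epoch
        assert fit.params["lambda_1"] == pytest.approx(0.0)
        assert fit.params["lambda_2"] == pytest.approx(1.0 / 3.0)

    def test_m1_reduces_to_constant(self, toy_tree):
        a = cd.fit_yule_piecewise(toy_tree, 1)
        b = cd.fit_yule_constant(toy_tree)
        assert a.params["lambda"] == pytest.approx(b.params["lambda"])
        assert a.llf == pytest.approx(b.llf)

    def test_k_counts(self):
        tree = cd.simulate_yule_tree(cd.ConstantRate(0.12), duration=30, seed=2)
        assert cd.fit_yule_piecewise(tree, 2).k == 3
        assert cd.fit_yule_piecewise(tree, 3).k == 5
        assert cd.fit_yule_piecewise(tree, 2, fixed_breakpoints=[10.0]).k == 2

    def test_nesting_never_reduces_loglik(self):
        for seed in (3, 4, 5):
            tree = cd.simulate_yule_tree(cd.ConstantRate(0.12), duration=35, seed=seed)
            l1 = cd.fit_yule_constant(tree).llf
            l2 = cd.fit_yule_piecewise(tree, 2).llf
            l3 = cd.fit_yule_piecewise(tree, 3).llf
            assert l2 >= l1 - 1e-6
            assert l3 >= l2 - 1e-6

    def test_too_many_epochs(self, toy_tree):
        with pytest.raises(DomainError):
            cd.fit_yule_piecewise(toy_tree, 5)

    def test_fitted_beats_random_parameters(self):
        tree = cd.simulate_yule_tree(cd.ConstantRate(0.12), duration=30, seed=6)
        fit = cd.fit_yule_piecewise(tree, 2)
        rng = np.random.default_rng(0)
        for _ in range(300):
            bp = float(rng.uniform(0.5, tree.root_age - 0.5))
            rates = rng.uniform(0.0, 0.6, size=2)
            ll = cd.yule_time_loglik(cd.PiecewiseRate(tuple(rates), (bp,)), tree)
            assert fit.llf >= ll - 1e-9


class TestFitYuleLogistic:
    def test_beats_grid_oracle(self):
        tree = cd.simulate_yule_tree(cd.ConstantRate(0.1), duration=30, seed=8)
        fit = cd.fit_yule_logistic(tree, seed=0)
        a_grid = np.linspace(fit.params["a"] - 0.1, fit.params["a"] + 0.1, 40)
        b_grid = np.linspace(fit.params["b"] - 1.0, fit.params["b"] + 1.0, 40)
        for a in a_grid:
            for b in b_grid:
                ll = cd.yule_time_loglik(cd.LogisticRate(a, b), tree)
                assert fit.llf >= ll - 1e-6

    def test_sign_recovery_on_decreasing_rate(self):
        hits = 0
        for s in range(10):
            tree = cd.simulate_yule_tree(
                cd.LogisticRate(-0.15, 0.5), duration=30, seed=100 + s
            )
            if tree.n < 10:
                continue
            fit = cd.fit_yule_logistic(tree, seed=0)
            hits += fit.params["a"] < 0
        assert hits >= 8

    def test_nested_model_calibration(self):
        """Against ~constant-rate trees the logistic gains < 2 logL units mostly."""
        ok = tot = 0
        for s in range(30):
            tree = cd.simulate_yule_tree(cd.ConstantRate(0.08), duration=40, seed=300 + s)
            if tree.n < 5:
                continue
            tot += 1
            gain = cd.fit_yule_logistic(tree, seed=0).llf - cd.fit_yule_constant(tree).llf
            assert gain >= -1e-6
            ok += gain < 2.0
        assert ok / tot >= 0.8


class TestFitYuleCovariate:
    def test_whole_tree_high_equals_constant(self, toy_tree):
        iv = cd.SeaLevelIntervals(((2.5, 0.0),))
        fit = cd.fit_yule_covariate(toy_tree, iv)
        assert fit.params["lambda_high"] == pytest.approx(0.2)

    def test_toy_pooled_counting(self, toy_tree):
        iv = cd.SeaLevelIntervals(((2.0, 1.0),))
        fit = cd.fit_yule_covariate(toy_tree, iv)
        assert fit.params["lambda_high"] == pytest.approx(0.0)
        assert fit.params["lambda_low"] == pytest.approx(1.0 / 3.0)
        assert fit.k == 2

    def test_empty_intervals_warns_and_degenerates(self, toy_tree):
        iv = cd.SeaLevelIntervals(())
        with pytest.warns(UserWarning, match="empty"):
            fit = cd.fit_yule_covariate(toy_tree, iv)
        assert fit.params["lambda_high"] == pytest.approx(0.2)


class TestBirthDeath:
    def test_mu_zero_matches_yule_loglik(self, random_trees):
        for tree in random_trees[:10]:
            bd = cd.BirthDeathModel(tree)
            lam = 0.5 * (tree.n - 2) / tree.total_branch_length() + 0.01
            assert bd.loglike(lam, 0.0) == pytest.approx(
                cd.yule_time_loglik(cd.ConstantRate(lam), tree), rel=1e-9
            )

    def test_fit_beats_grid_oracle(self):
        tree = cd.simulate_yule_tree(cd.ConstantRate(0.1), duration=35, seed=9)
        fit = cd.fit_birth_death_constant(tree)
        bd = cd.BirthDeathModel(tree)
        lam0, mu0 = fit.params["lambda"], fit.params["mu"]
        for lam in np.linspace(max(lam0 - 0.05, 1e-4), lam0 + 0.05, 50):
            for mu in np.linspace(0.0, mu0 + 0.05, 50):
                if mu >= lam:
                    continue
                assert fit.llf >= bd.loglike(lam, mu) - 1e-6

    def test_extinction_boundary_on_pure_birth_trees(self):
        """μ̂ frequently sits at its 0 boundary when the truth is pure birth.

        For a boundary-true parameter the estimate is clipped to 0 roughly
        half the time (verified against ape::birthdeath behaviour), so the
        boundary fraction must be substantial and the median estimate 0.
        """
        mus = []
        for s in range(40):
            tree = cd.simulate_yule_tree(cd.ConstantRate(0.08), duration=45, seed=700 + s)
            if tree.n < 10:
                continue
            mus.append(cd.fit_birth_death_constant(tree).params["mu"])
        mus = np.array(mus)
        assert np.mean(mus < 1e-6) >= 0.35
        assert np.median(mus) < 1e-6


class TestAicLrt:
    @pytest.mark.parametrize(
        "logL,k,expect",
        [(62.27, 1, -122.54), (71.68, 5, -133.36), (0.0, 0, 0.0)],
    )
    def test_aic(self, logL, k, expect):
        assert cd.aic(logL, k) == pytest.approx(expect)

    def test_lrt_identity(self):
        lr, p = cd.lrt_clock(-10.0, -10.0)
        assert lr == 0.0
        assert p == pytest.approx(1.0)

    def test_lrt_warns_when_nonclock_worse(self):
        with pytest.warns(UserWarning):
            lr, p = cd.lrt_clock(-10.0, -11.0)
        assert lr == pytest.approx(-2.0)
        assert p == pytest.approx(1.0)

    def test_lrt_sign_flips_with_arguments(self):
        lr1, _ = cd.lrt_clock(-12.0, -10.0)
        with pytest.warns(UserWarning):
            lr2, _ = cd.lrt_clock(-10.0, -12.0)
        assert lr1 == pytest.approx(-lr2)


class TestLTT:
    def test_toy_curve(self, toy_tree):
        c = cd.ltt_curve(toy_tree)
        np.testing.assert_allclose(c.times, [0.0, 1.0])
        np.testing.assert_allclose(c.counts, [2, 3])

    def test_curve_is_cumulative_recount(self, random_trees):
        for tree in random_trees[:20]:
            c = cd.ltt_curve(tree)
            assert c.counts[-1] == tree.n
            expect_times = np.sort(tree.root_age - tree.branching_times())
            np.testing.assert_allclose(c.times, expect_times)
            assert (np.diff(c.counts) >= 0).all()

    def test_envelope_contains_median_of_own_sims(self):
        tree = cd.simulate_yule_tree(cd.ConstantRate(0.1), duration=30, seed=21)
        fit = cd.fit_yule_constant(tree)
        env = cd.ltt_envelope(tree, fit, reps=150, seed=1)
        df = env.to_frame()
        # envelope quantiles must bracket each other and be ordered
        assert (df["lower"] <= df["upper"]).all()
        # observed curve mostly inside its own fitted-model envelope
        inside = ((df["count"] >= df["lower"]) & (df["count"] <= df["upper"])).mean()
        assert inside >= 0.8

    def test_envelope_requires_enough_reps(self, toy_tree):
        fit = cd.fit_yule_constant(toy_tree)
        with pytest.raises(DomainError):
            cd.ltt_envelope(toy_tree, fit, reps=10, seed=0)


class TestWindowRates:
    def test_toy_windows(self, toy_tree):
        df = cd.window_rates(toy_tree, width=1.0)
        np.testing.assert_allclose(df["rate"], [0.0, 1.0 / 3.0])
        np.testing.assert_allclose(df["lineage_time"], [2.0, 3.0])

    def test_wide_window_collapses_to_constant_mle(self, random_trees):
        for tree in random_trees[:10]:
            df = cd.window_rates(tree, width=tree.root_age * 2)
            assert len(df) == 1
            expect = (tree.n - 2) / tree.total_branch_length()
            assert df["rate"].iloc[0] == pytest.approx(expect)

    def test_window_rates_near_truth_on_large_tree(self):
        lam = 0.12
        tree = cd.simulate_yule_tree(cd.ConstantRate(lam), n_tips=500, seed=31)
        df = cd.window_rates(tree, width=10.0)
        ok = 0
        used = 0
        for _, row in df.iterrows():
            if row["events"] < 1 or not np.isfinite(row["rate"]):
                continue
            used += 1
            se = lam / np.sqrt(max(row["events"], 1))
            ok += abs(row["rate"] - lam) <= 2.5 * se
        assert used >= 2
        assert ok / used >= 0.6


class TestCompareModels:
    def test_table_contains_suite_and_flags_best(self):
        tree = cd.simulate_yule_tree(cd.ConstantRate(0.1), duration=30, seed=41)
        table, fits = cd.compare_models(
            tree, intervals=cd.sea_level_fixture("toy"), seed=0
        )
        assert set(table["model"]) == {
            "yule",
            "birth_death",
            "sea_level",
            "logistic",
            "one_breakpoint",
            "two_breakpoints",
        }
        assert table["best"].sum() == 1
        best = table.loc[table["best"], "AIC"].iloc[0]
        assert best == pytest.approx(table["AIC"].min())
        for _, row in table.iterrows():
            assert row["AIC"] == pytest.approx(-2 * row["logL"] + 2 * row["k"])
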