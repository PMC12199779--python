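import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bayesize.inference import PosteriorDraws, SamplerConfig
from bayesize.model_spec import FamilySpec, LinearTerm, ModelSpec, PriorSpec
from bayesize.planning import (
    Goal, PlanningConfig, TTestParams, estimate_power_at_n, evaluate_goal,
    find_min_sample_size, simulate_dataset, t_test_sample_size,
    two_group_nb_scenario, wilson_interval,
)


def _known_sigma_normal_models(sigma=1.0, mu=0.0):
    """Data-generation + inference pair for an intercept-only normal model
    with fixed sigma; the posterior width has a closed form."""
    dg = ModelSpec("y", [LinearTerm("intercept")], FamilySpec("normal"),
                   priors=[PriorSpec("intercept", "point", {"value": mu}),
                           PriorSpec("sigma", "point", {"value": sigma})],
                   role="data_generation")
    inf = ModelSpec("y", [LinearTerm("intercept")], FamilySpec("normal"),
                    priors=[PriorSpec("intercept", "normal",
                                      {"loc": 0.0, "scale": 100.0}),
                            PriorSpec("sigma", "point", {"value": sigma})])
    return dg, inf


class TestSimulateDataset:
    def test_empty_design_gives_empty_table(self):
        dg, _ = two_group_nb_scenario(2.0, 4.86, 4.49)
        t = simulate_dataset(dg, {"A": 0, "B": 0}, seed=1)
        assert t.n_rows == 0

    def test_nb_moments_match_formula(self):
        # NB(mu=10, phi=2): Var = 10 + 100/2 = 60
        dg = ModelSpec("y", [LinearTerm("intercept")],
                       FamilySpec("negative_binomial"),
                       priors=[PriorSpec("intercept", "point",
                                         {"value": float(np.log(10))}),
                               PriorSpec("phi", "point", {"value": 2.0})],
                       role="data_generation")
        t = simulate_dataset(dg, 100_000, seed=2)
        y = t.column("y").to_numpy()
        assert y.mean() == pytest.approx(10.0, rel=0.05)
        assert y.var(ddof=1) == pytest.approx(60.0, rel=0.05)

    def test_same_seed_same_table(self):
        dg, _ = two_group_nb_scenario(2.0, 4.86, 4.49)
        a = simulate_dataset(dg, {"A": 20, "B": 20}, seed=7)
        b = simulate_dataset(dg, {"A": 20, "B": 20}, seed=7)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_group_sizes_respected(self):
        dg, _ = two_group_nb_scenario(2.0, 4.86, 4.49)
        t = simulate_dataset(dg, {"A": 5, "B": 9}, seed=3)
        counts = t.column("strain").value_counts()
        assert counts["A"] == 5 and counts["B"] == 9

    def test_free_parameters_rejected(self):
        inf = ModelSpec("y", [LinearTerm("intercept")], FamilySpec("poisson"),
                        priors=[PriorSpec("intercept", "normal", {"scale": 1.0})])
        with pytest.raises(ValueError):
            simulate_dataset(inf, 10, seed=0)


class TestEvaluateGoal:
    def _draws(self, values):
        model = ModelSpec("y", [LinearTerm("intercept")], FamilySpec("normal"),
                          priors=[PriorSpec("sigma", "point", {"value": 1.0})])
        arr = np.asarray(values, float).reshape(2, -1, 1)
        return PosteriorDraws(arr, ["intercept"], model, "", 0,
                              SamplerConfig(seed=0))

    def test_interval_inside_rope_is_not_excluded(self):
        draws = self._draws(np.linspace(-0.1, 0.1, 1000))
        goal = Goal("rope_exclusion", "intercept", rope_lower=-0.2, rope_upper=0.2)
        assert evaluate_goal(draws, goal) is False

    def test_interval_beyond_rope_is_excluded(self):
        draws = self._draws(np.linspace(0.5, 0.9, 1000))
        goal = Goal("rope_exclusion", "intercept", rope_lower=-0.1, rope_upper=0.1)
        assert evaluate_goal(draws, goal) is True

    def test_precision_goal_uses_interval_width(self):
        draws = self._draws(np.linspace(2.0, 2.8, 1000))
        assert evaluate_goal(draws, Goal("precision", "intercept",
                                         max_width=1.0)) is True
        assert evaluate_goal(draws, Goal("precision", "intercept",
                                         max_width=0.5)) is False

    def test_missing_target_rejected(self):
        draws = self._draws(np.zeros(1000))
        with pytest.raises(KeyError):
            evaluate_goal(draws, Goal("precision", "nope", max_width=1.0))


class TestEstimatePower:
    FAST = SamplerConfig(2, 200, 300, seed=0)

    def test_impossible_goal_has_zero_power(self):
        dg, inf = _known_sigma_normal_models()
        goal = Goal("precision", "intercept", max_width=0.0)
        est = estimate_power_at_n(dg, inf, goal, 10, 20, seed=1, sampler=self.FAST)
        assert est.power == 0.0

    def test_trivial_goal_has_full_power(self):
        dg, inf = _known_sigma_normal_models()
        goal = Goal("precision", "intercept", max_width=np.inf)
        est = estimate_power_at_n(dg, inf, goal, 10, 20, seed=1, sampler=self.FAST)
        assert est.power == 1.0
        assert est.ci_upper == 1.0

    def test_power_jump_across_closed_form_n(self):
        """Known sigma=1, width 0.4 at mass 0.95: posterior width is
        2*1.96/sqrt(n), so the goal flips near n=(2*1.96/0.4)^2 ~ 96."""
        dg, inf = _known_sigma_normal_models()
        goal = Goal("precision", "intercept", interval_method="eti", max_width=0.4)
        sampler = SamplerConfig(2, 300, 1500, seed=0)
        low = estimate_power_at_n(dg, inf, goal, 40, 20, seed=2, sampler=sampler)
        high = estimate_power_at_n(dg, inf, goal, 200, 20, seed=2, sampler=sampler)
        assert low.power <= 0.2
        assert high.power >= 0.8

    def test_wilson_bounds_bracket_estimate(self):
        lo, hi = wilson_interval(8, 10)
        assert lo <= 0.8 <= hi
        assert wilson_interval(0, 10)[0] == 0.0


class TestFindMinSampleSize:
    def test_closed_form_normal_precision_scenario(self):
        """Recommended n within one grid step of (2*z*sigma/width)^2 = 96."""
        dg, inf = _known_sigma_normal_models()
        goal = Goal("precision", "intercept", interval_method="eti", max_width=0.4)
        config = PlanningConfig([40, 60, 80, 100, 120, 140], n_replicates=40,
                                power_target=0.8, seed=5,
                                sampler=SamplerConfig(2, 300, 800, seed=0))
        res = find_min_sample_size(dg, inf, goal, config)
        assert res.recommended_n in (80, 100, 120)
        assert not res.n_is_per_group

    def test_power_monotone_in_n(self):
        dg, inf = _known_sigma_normal_models()
        goal = Goal("precision", "intercept", interval_method="eti", max_width=0.4)
        powers = [estimate_power_at_n(dg, inf, goal, n, 30, seed=9,
                                      sampler=SamplerConfig(2, 300, 800, seed=0)).power
                  for n in (40, 70, 100, 130)]
        rho = stats.spearmanr(np.arange(4), powers).statistic
        assert rho >= 0.9

    def test_goal_unreachable_returns_none(self):
        dg, inf = _known_sigma_normal_models()
        goal = Goal("precision", "intercept", max_width=0.001)
        config = PlanningConfig([5, 10], n_replicates=20, seed=1,
                                sampler=SamplerConfig(2, 200, 300, seed=0))
        res = find_min_sample_size(dg, inf, goal, config)
        assert res.recommended_n is None
        assert len(res.estimates) >= 1

    def test_immediate_achievement_recommends_smallest(self):
        dg, inf = _known_sigma_normal_models()
        goal = Goal("precision", "intercept", max_width=np.inf)
        config = PlanningConfig([5, 10, 20], n_replicates=20, seed=1,
                                sampler=SamplerConfig(2, 200, 300, seed=0))
        res = find_min_sample_size(dg, inf, goal, config)
        assert res.recommended_n == 5


class TestTTestSampleSize:
    def test_large_effect_gives_design_floor(self):
        assert t_test_sample_size(TTestParams(10.0, 1.0)) == 4

    def test_agreement_with_statsmodels_power_solver(self):
        from statsmodels.stats.power import TTestIndPower

        solver = TTestIndPower()
        rng = np.random.default_rng(0)
        for _ in range(20):
            d = rng.uniform(0.3, 2.0)
            alpha = rng.uniform(0.01, 0.1)
            power = rng.uniform(0.5, 0.95)
            ours = t_test_sample_size(TTestParams(d, 1.0, alpha=alpha, power=power))
            n_ref = solver.solve_power(effect_size=d, alpha=alpha, power=power,
                                       alternative="two-sided")
            assert ours == int(np.ceil(2 * n_ref - 1e-9)) or \
                abs(ours - 2 * n_ref) < 1.01

    def test_power_below_alpha_has_no_solution(self):
        with pytest.raises(ValueError):
            TTestParams(1.0, 1.0, alpha=0.05, power=0.0)


class TestNbScenario:
    def test_moment_matching(self):
        dg, phi = two_group_nb_scenario(0.5, 4.86, 4.49)
        mu_a, mu_b = 0.5, 5.36
        var_a = mu_a + mu_a**2 / phi
        var_b = mu_b + mu_b**2 / phi
        assert (var_a + var_b) / 2 == pytest.approx(4.49**2, rel=1e-9)
        params = dg.fixed_parameters()
        assert np.exp(params["intercept"]) == pytest.approx(mu_a)
        assert np.exp(params["intercept"] + params["strain[B]"]) == \
            pytest.approx(mu_b)

    def test_underdispersed_target_rejected(self):
        with pytest.raises(ValueError):
            two_group_nb_scenario(30.0, 4.86, 4.49)
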