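import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln
from scipy.stats import chisquare, norm

from bayesize import DataTable
from bayesize.inference import (
    SamplerConfig, compute_rhat, fit_model, log_posterior, pointwise_loglik,
)
from bayesize.model_spec import FamilySpec, LinearTerm, ModelSpec, PriorSpec


def _poisson_intercept_model(prior_scale=10.0):
    return ModelSpec("y", [LinearTerm("intercept")], FamilySpec("poisson"),
                     priors=[PriorSpec("intercept", "normal",
                                       {"loc": 0.0, "scale": prior_scale})])


class TestLogPosterior:
    def test_poisson_closed_form_single_observation(self):
        data = DataTable(pd.DataFrame({"y": [2.0]}))
        model = _poisson_intercept_model()
        eta = 0.7
        got = log_posterior(model, data, {"intercept": eta})
        loglik = 2 * eta - np.exp(eta) - gammaln(3.0)
        prior = norm.logpdf(eta, 0, 10)
        assert got == pytest.approx(loglik + prior, rel=1e-10)

    def test_zero_observations_equals_log_prior(self):
        data = DataTable(pd.DataFrame({"y": pd.Series(dtype=float)}))
        model = _poisson_intercept_model()
        got = log_posterior(model, data, {"intercept": 1.3})
        assert got == pytest.approx(norm.logpdf(1.3, 0, 10))

    def test_nb_approaches_poisson_as_phi_grows(self):
        y = np.array([0.0, 3.0, 5.0, 2.0, 7.0])
        data = DataTable(pd.DataFrame({"y": y}))
        pois = _poisson_intercept_model()
        nb = ModelSpec("y", [LinearTerm("intercept")],
                       FamilySpec("negative_binomial"),
                       priors=[PriorSpec("intercept", "normal",
                                         {"loc": 0.0, "scale": 10.0}),
                               PriorSpec("phi", "flat")])
        lp_pois = log_posterior(pois, data, {"intercept": 1.1})
        lp_nb = log_posterior(nb, data, {"intercept": 1.1, "phi": 1e6})
        assert lp_nb == pytest.approx(lp_pois, abs=1e-3)

    def test_out_of_support_is_minus_inf(self):
        data = DataTable(pd.DataFrame({"y": [1.0, 2.0]}))
        model = ModelSpec("y", [LinearTerm("intercept")], FamilySpec("normal"),
                          priors=[PriorSpec("intercept", "normal", {"scale": 5.0}),
                                  PriorSpec("sigma", "exponential", {"rate": 1.0})])
        assert log_posterior(model, data, {"intercept": 0.0, "sigma": -1.0}) == -np.inf


class TestFitModel:
    def test_conjugate_posterior_recovered(self, conjugate_normal_fit):
        f = conjugate_normal_fit
        mu = f["draws"].extract("intercept")
        n_eff = min(f["diag"].ess_bulk["intercept"], mu.size)
        mc_se = f["post_sd"] / np.sqrt(n_eff)
        assert mu.mean() == pytest.approx(f["post_mean"], abs=3 * mc_se)
        assert mu.std() == pytest.approx(f["post_sd"], rel=0.1)
        assert f["diag"].passed

    def test_binomial_logit_posterior_symmetric_about_logit_phat(self):
        # balanced successes/failures + symmetric prior => symmetric posterior
        data = DataTable(pd.DataFrame({"y": [1.0] * 12 + [0.0] * 12}))
        model = ModelSpec("y", [LinearTerm("intercept")],
                          FamilySpec("binomial", aux_params={"trials": 1}),
                          priors=[PriorSpec("intercept", "normal",
                                            {"loc": 0.0, "scale": 2.5})])
        draws, diag = fit_model(model, data, SamplerConfig(seed=21))
        a = draws.extract("intercept")
        se = a.std() / np.sqrt(diag.ess_bulk["intercept"])
        assert np.median(a) == pytest.approx(0.0, abs=4 * se)
        skew = np.mean(((a - a.mean()) / a.std()) ** 3)
        assert abs(skew) < 0.2

    def test_identical_seed_gives_bitwise_identical_draws(self, conjugate_normal_fit):
        f = conjugate_normal_fit
        again, _ = fit_model(f["model"], f["data"], SamplerConfig(seed=7))
        np.testing.assert_array_equal(again.draws, f["draws"].draws)

    def test_posterior_contracts_with_sample_size(self):
        rng = np.random.default_rng(99)
        sds = []
        for n in (20, 80, 320):
            y = rng.normal(1.0, 2.0, n)
            data = DataTable(pd.DataFrame({"y": y}))
            model = ModelSpec("y", [LinearTerm("intercept")], FamilySpec("normal"))
            draws, _ = fit_model(model, data, SamplerConfig(2, 500, 1000, seed=n))
            sds.append(draws.extract("intercept").std())
        assert sds[0] > sds[1] > sds[2]

    def test_prior_recovered_with_zero_observations(self):
        data = DataTable(pd.DataFrame({"y": pd.Series(dtype=float)}))
        model = ModelSpec("y", [LinearTerm("intercept")], FamilySpec("normal"),
                          priors=[PriorSpec("intercept", "normal",
                                            {"loc": 2.0, "scale": 3.0}),
                                  PriorSpec("sigma", "point", {"value": 1.0})])
        draws, _ = fit_model(model, data, SamplerConfig(4, 800, 2000, seed=5))
        mu = draws.extract("intercept")
        q = np.quantile(mu, [0.25, 0.5, 0.75])
        expected = norm.ppf([0.25, 0.5, 0.75], 2.0, 3.0)
        np.testing.assert_allclose(q, expected, atol=0.25)

    def test_constant_response_with_autoscaled_priors_rejected(self):
        data = DataTable(pd.DataFrame({"y": [3.0] * 10}))
        model = ModelSpec("y", [LinearTerm("intercept")], FamilySpec("normal"))
        with pytest.raises(ValueError):
            fit_model(model, data, SamplerConfig(seed=0))

    def test_missing_values_rejected(self):
        data = DataTable(pd.DataFrame({"y": [1.0, np.nan, 2.0]}))
        model = ModelSpec("y", [LinearTerm("intercept")], FamilySpec("normal"))
        with pytest.raises(ValueError, match="complete_cases"):
            fit_model(model, data, SamplerConfig(seed=0))


class TestSimulationBasedCalibration:
    def test_rank_histogram_uniform_for_normal_mean(self):
        """Ranks of the true parameter among thinned posterior draws should
        be uniform when data are generated from the prior (200 replicates,
        chi-square at alpha=0.01)."""
        n_rep, n_bins = 200, 10
        rng = np.random.default_rng(2718)
        data_cfg = SamplerConfig(2, 300, 500, seed=0)
        ranks = []
        for r in range(n_rep):
            mu_true = rng.normal(0.0, 2.0)
            y = rng.normal(mu_true, 1.0, 10)
            data = DataTable(pd.DataFrame({"y": y}))
            model = ModelSpec(
                "y", [LinearTerm("intercept")], FamilySpec("normal"),
                priors=[PriorSpec("intercept", "normal", {"loc": 0.0, "scale": 2.0}),
                        PriorSpec("sigma", "point", {"value": 1.0})])
            cfg = SamplerConfig(data_cfg.n_chains, data_cfg.n_warmup,
                                data_cfg.n_draws, seed=r)
            draws, _ = fit_model(model, data, cfg)
            thinned = draws.extract("intercept")[::25]  # beat autocorrelation
            ranks.append(np.sum(thinned < mu_true) / (thinned.size + 1))
        counts, _ = np.histogram(ranks, bins=n_bins, range=(0, 1))
        _, p = chisquare(counts)
        assert p > 0.01


class TestComputeRhat:
    def test_identical_chains_near_one(self):
        rng = np.random.default_rng(0)
        chain = rng.standard_normal(1000)
        assert compute_rhat(np.stack([chain, chain])) <= 1.001

    def test_offset_chains_flagged(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal(500)
        assert compute_rhat(np.stack([a, a + 10.0])) > 1.5

    def test_white_noise_chains_near_one(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((4, 1000))
        assert 0.99 <= compute_rhat(x) <= 1.01

    def test_constant_parameter_reported_as_nan(self):
        assert np.isnan(compute_rhat(np.ones((2, 100))))

    def test_agrees_with_arviz_split_rhat(self):
        import arviz as az
        rng = np.random.default_rng(3)
        x = rng.standard_normal((4, 500)) + rng.normal(0, 0.05, size=(4, 1))
        ours = compute_rhat(x)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = float(az.rhat(x, method="split"))
        assert ours == pytest.approx(ref, abs=0.005)


class TestPointwiseLoglik:
    def test_rows_sum_to_total_loglik(self, conjugate_normal_fit):
        f = conjugate_normal_fit
        ll = pointwise_loglik(f["draws"], f["data"])
        assert ll.shape == (f["draws"].flat().shape[0], 20)
        # check three draws against the closed-form normal density
        for s in (0, 100, 4000):
            mu = f["draws"].flat()[s, 0]
            expected = norm.logpdf(f["y"], mu, 2.0)
            np.testing.assert_allclose(ll[s], expected, rtol=1e-10)

    def test_mismatched_data_rejected(self, conjugate_normal_fit):
        f = conjugate_normal_fit
        other = DataTable(pd.DataFrame({"y": f["y"] + 1.0}))
        with pytest.raises(ValueError, match="digest|match"):
            pointwise_loglik(f["draws"], other)

    def test_duplicated_row_doubles_its_contribution(self):
        rng = np.random.default_rng(12)
        y = rng.normal(0, 1, 10)
        model = ModelSpec("y", [LinearTerm("intercept")], FamilySpec("normal"),
                          priors=[PriorSpec("intercept", "normal", {"scale": 5.0}),
                                  PriorSpec("sigma", "point", {"value": 1.0})])
        d1 = DataTable(pd.DataFrame({"y": y}))
        d2 = DataTable(pd.DataFrame({"y": np.concatenate([y, y[:1]])}))
        cfg = SamplerConfig(2, 200, 300, seed=1)
        ll1 = pointwise_loglik(*_refit(model, d1, cfg))
        ll2 = pointwise_loglik(*_refit(model, d2, cfg))
        np.testing.assert_allclose(ll2[:, -1], ll2[:, 0], rtol=1e-12)
        assert ll2.shape[1] == ll1.shape[1] + 1


def _refit(model, data, cfg):
    draws, _ = fit_model(model, data, cfg)
    return draws, data
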