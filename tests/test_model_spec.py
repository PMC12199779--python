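import numpy as np
import pandas as pd
import pytest

from bayesize.data_model import DataTable, VariableMeta
from bayesize.families import FAMILIES, get_link
from bayesize.model_spec import (
    FamilySpec, LinearTerm, ModelSpec, PriorSpec, build_design,
    compatible_families, default_priors, linear_predictor, parse_formula,
    validate_model,
)


class TestFamilySpec:
    def test_default_link_is_canonical(self):
        assert FamilySpec("poisson").link == "log"
        assert FamilySpec("normal").link == "identity"
        assert FamilySpec("beta").link == "logit"

    def test_incompatible_link_rejected(self):
        with pytest.raises(ValueError, match="link"):
            FamilySpec("poisson", link="identity")

    def test_nonpositive_aux_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            FamilySpec("negative_binomial", aux_params={"phi": -1.0})

    def test_binomial_requires_trials(self):
        with pytest.raises(ValueError, match="trials"):
            FamilySpec("binomial")

    @pytest.mark.parametrize("name", sorted(FAMILIES))
    def test_inverse_link_lands_in_mean_support(self, name):
        fam = FAMILIES[name]
        link = get_link(fam.default_link)
        eta = np.linspace(-20, 20, 41)
        mu = link.inverse(eta)
        lo, hi = fam.mean_interval
        assert np.all(mu >= lo) and np.all(mu <= hi)


class TestCompatibleFamilies:
    def test_count_gets_count_families(self):
        meta = VariableMeta("y", role="response", kind="count")
        names = {f.family for f in compatible_families(meta)}
        assert names == {"poisson", "negative_binomial"}

    def test_count_with_known_trials_adds_binomial(self):
        meta = VariableMeta("y", role="response", kind="count", upper_bound=10)
        assert "binomial" in {f.family for f in compatible_families(meta)}

    def test_proportion_gets_beta(self):
        meta = VariableMeta("y", role="response", kind="proportion")
        assert {f.family for f in compatible_families(meta)} == {"beta"}

    def test_positive_continuous_families(self):
        meta = VariableMeta("y", role="response", kind="continuous", lower_bound=0)
        names = {f.family for f in compatible_families(meta)}
        assert names == {"gamma", "lognormal", "exponential", "inverse_gaussian"}

    def test_all_returned_families_accept_the_kind(self):
        for kind in ("count", "proportion", "binary", "continuous"):
            meta = VariableMeta("y", role="response", kind=kind)
            for fs in compatible_families(meta):
                assert kind in fs.family_obj.response_kinds


class TestValidateModel:
    def _metas(self):
        return [VariableMeta("y", role="response", kind="count"),
                VariableMeta("g", role="predictor", kind="categorical")]

    def test_valid_count_model_is_clean(self):
        m = ModelSpec("y", [LinearTerm("intercept"), LinearTerm("main_effect", ("g",))],
                      FamilySpec("poisson"), categorical_levels={"g": ("a", "b")})
        assert validate_model(m, self._metas()) == []

    def test_family_kind_mismatch_reported(self):
        metas = [VariableMeta("y", role="response", kind="continuous")]
        m = ModelSpec("y", [LinearTerm("intercept")], FamilySpec("poisson"))
        assert any("incompatible" in f for f in validate_model(m, metas))

    def test_interaction_needs_two_variables(self):
        with pytest.raises(ValueError):
            LinearTerm("interaction", ("g",))


class TestLinearPredictor:
    def test_intercept_only_log_link(self):
        m = ModelSpec("y", [LinearTerm("intercept")], FamilySpec("poisson"))
        eta = linear_predictor(m, {"intercept": 1.2}, {})
        assert eta == pytest.approx(1.2)
        assert np.exp(eta) == pytest.approx(np.e ** 1.2)

    def test_reference_level_contributes_zero(self):
        m = ModelSpec("y", [LinearTerm("intercept"), LinearTerm("main_effect", ("g",))],
                      FamilySpec("poisson"), categorical_levels={"g": ("a", "b")})
        params = {"intercept": 0.5, "g[b]": 1.0}
        assert linear_predictor(m, params, {"g": "a"}) == pytest.approx(0.5)
        assert linear_predictor(m, params, {"g": "b"}) == pytest.approx(1.5)

    def test_log_link_mean_ratio_is_exp_beta(self):
        m = ModelSpec("y", [LinearTerm("intercept"), LinearTerm("main_effect", ("s",))],
                      FamilySpec("negative_binomial"),
                      categorical_levels={"s": ("A", "B")})
        params = {"intercept": 0.7, "s[B]": 0.9}
        mean_a = np.exp(linear_predictor(m, params, {"s": "A"}))
        mean_b = np.exp(linear_predictor(m, params, {"s": "B"}))
        assert mean_b / mean_a == pytest.approx(np.exp(0.9))

    def test_unknown_level_rejected(self):
        m = ModelSpec("y", [LinearTerm("main_effect", ("g",))],
                      FamilySpec("poisson"), categorical_levels={"g": ("a", "b")})
        with pytest.raises(ValueError, match="unknown level"):
            linear_predictor(m, {"g[b]": 1.0}, {"g": "zzz"})


class TestDefaultPriors:
    @pytest.fixture
    def table(self):
        rng = np.random.default_rng(3)
        y = np.array([1.1, 2.0, 0.5, 3.3, 2.2, 1.7, 0.9, 2.8, 1.4, 2.6])
        x = rng.normal(size=10)
        x = (x - x.mean()) / x.std(ddof=1)  # standardized predictor
        return DataTable(pd.DataFrame({"y": y, "x": x}))

    def test_intercept_only_normal_autoscaling(self, table):
        m = ModelSpec("y", [LinearTerm("intercept")], FamilySpec("normal"))
        priors = {p.parameter: p for p in default_priors(m, table)}
        y = table.column("y").to_numpy()
        assert priors["intercept"].hyperparams["loc"] == pytest.approx(y.mean())
        assert priors["intercept"].hyperparams["scale"] == pytest.approx(
            2.5 * y.std(ddof=1))
        assert priors["sigma"].distribution == "exponential"
        assert priors["sigma"].hyperparams["rate"] == pytest.approx(
            1 / y.std(ddof=1))

    def test_standardized_coefficient_scale(self, table):
        m = ModelSpec("y", [LinearTerm("intercept"), LinearTerm("main_effect", ("x",))],
                      FamilySpec("normal"))
        priors = {p.parameter: p for p in default_priors(m, table)}
        y = table.column("y").to_numpy()
        assert priors["x"].hyperparams["loc"] == 0.0
        assert priors["x"].hyperparams["scale"] == pytest.approx(
            2.5 * y.std(ddof=1), rel=1e-9)

    def test_nb_dispersion_prior_has_positive_support(self):
        counts = DataTable(pd.DataFrame({"y": [0, 3, 5, 2, 8, 1, 4, 9, 2, 3]}))
        m = ModelSpec("y", [LinearTerm("intercept")], FamilySpec("negative_binomial"))
        priors = {p.parameter: p for p in default_priors(m, counts)}
        assert priors["phi"].distribution in ("exponential", "half_normal")

    def test_row_order_invariance(self, table):
        m = ModelSpec("y", [LinearTerm("intercept"), LinearTerm("main_effect", ("x",))],
                      FamilySpec("normal"))
        shuffled = DataTable(table.df.sample(frac=1, random_state=0))
        a = [p.to_dict() for p in default_priors(m, table)]
        b = [p.to_dict() for p in default_priors(m, shuffled)]
        assert a == b

    def test_zero_variance_response_rejected(self):
        flat = DataTable(pd.DataFrame({"y": [2.0] * 6}))
        m = ModelSpec("y", [LinearTerm("intercept")], FamilySpec("normal"))
        with pytest.raises(ValueError, match="zero-variance"):
            default_priors(m, flat)


class TestDesignAndFormula:
    def test_formula_round_trip_terms(self):
        m = parse_formula("y ~ a + b + a:b", "normal")
        kinds = [t.kind for t in m.terms]
        assert kinds == ["intercept", "main_effect", "main_effect", "interaction"]

    def test_design_matrix_dummy_coding(self):
        m = ModelSpec("y", [LinearTerm("intercept"), LinearTerm("main_effect", ("g",))],
                      FamilySpec("normal"), categorical_levels={"g": ("b", "a", "c")})
        df = pd.DataFrame({"g": ["a", "b", "c"]})
        X, names = build_design(m, df)
        assert names == ["intercept", "g[b]", "g[c]"]  # 'a' is reference
        np.testing.assert_array_equal(X, [[1, 0, 0], [1, 1, 0], [1, 0, 1]])

    def test_model_spec_json_round_trip(self):
        m = ModelSpec("y", [LinearTerm("intercept"), LinearTerm("main_effect", ("g",))],
                      FamilySpec("negative_binomial"),
                      priors=[PriorSpec("phi", "exponential", {"rate": 1.0})],
                      categorical_levels={"g": ("a", "b")})
        assert ModelSpec.from_dict(m.to_dict()).to_dict() == m.to_dict()

    def test_data_generation_role_requires_point_priors(self):
        with pytest.raises(ValueError, match="point priors"):
            ModelSpec("y", [LinearTerm("intercept")], FamilySpec("poisson"),
                      role="data_generation")
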