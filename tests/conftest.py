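import warnings

import numpy as np
import pandas as pd
import pytest

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

from bayesize import DataTable, SamplerConfig, fit_model
from bayesize.model_spec import FamilySpec, LinearTerm, ModelSpec, PriorSpec


@pytest.fixture(scope="session")
def conjugate_normal_fit():
    """Known-sigma normal fit with an analytically tractable posterior.

    y_i ~ N(mu, sigma=2), prior mu ~ N(0, 10): posterior is normal with
    precision 1/100 + n/4.
    """
    rng = np.random.default_rng(42)
    y = rng.normal(5.0, 2.0, 20)
    data = DataTable(pd.DataFrame({"y": y}))
    model = ModelSpec(
        "y", [LinearTerm("intercept")], FamilySpec("normal"),
        priors=[PriorSpec("intercept", "normal", {"loc": 0.0, "scale": 10.0}),
                PriorSpec("sigma", "point", {"value": 2.0})])
    post, diag = fit_model(model, data, SamplerConfig(seed=7))
    prec = 1 / 100 + len(y) / 4
    return {
        "y": y, "data": data, "model": model, "draws": post, "diag": diag,
        "post_mean": (y.sum() / 4) / prec, "post_sd": prec ** -0.5,
    }


@pytest.fixture(scope="session")
def nb_two_group_fit():
    """Negative-binomial two-group fit on simulated overdispersed counts."""
    from bayesize import simulate_dataset, two_group_nb_scenario

    dg, phi = two_group_nb_scenario(2.5, 4.86, 4.49)
    data = simulate_dataset(dg, {"A": 40, "B": 40}, seed=11)
    inf = ModelSpec("center_entries", list(dg.terms),
                    FamilySpec("negative_binomial"),
                    categorical_levels=dg.categorical_levels)
    post, diag = fit_model(inf, data, SamplerConfig(seed=13))
    return {"dg": dg, "phi": phi, "data": data, "model": inf,
            "draws": post, "diag": diag,
            "true_beta": float(np.log(7.36 / 2.5))}
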