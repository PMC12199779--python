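"""Model criticism: posterior predictive checks and PSIS-LOO comparison.

Posterior predictive checks replicate the observed dataset from draws of
the fitted model and compare a summary statistic of the observations with
its replicated distribution; a two-sided tail probability near zero flags
misfit in that statistic.

Model comparison uses leave-one-out cross-validation approximated by
Pareto-smoothed importance sampling (PSIS): per observation, the raw
importance ratios are the reciprocal pointwise likelihoods, the largest
``M = min(0.2 S, 3 sqrt(S))`` ratios are replaced by quantiles of a
generalized Pareto distribution fitted to them (Zhang–Stephens estimator),
weights are truncated at the raw maximum and normalized, and the expected
log pointwise predictive density (elpd) follows as a weighted average.
The per-observation Pareto shape k-hat diagnoses reliability (alert at
k > 0.7).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .data_model import DataTable
from .inference import PosteriorDraws

__all__ = [
    "PPCResult", "LooResult", "ModelComparison", "PPC_STATISTICS",
    "posterior_predictive_replicates", "ppc_statistic",
    "fit_generalized_pareto", "psis_loo", "compare_models",
]

PARETO_K_THRESHOLD = 0.7

PPC_STATISTICS = {
    "mean": lambda y: float(np.mean(y)),
    "sd": lambda y: float(np.std(y, ddof=1)),
    "max": lambda y: float(np.max(y)),
    "proportion_zero": lambda y: float(np.mean(np.asarray(y) == 0)),
}


@dataclass
class PPCResult:
    statistic: str
    observed: float
    replicated: np.ndarray
    tail_probability: float

    def to_dict(self) -> dict:
        return {"statistic": self.statistic, "observed": self.observed,
                "replicated": [float(v) for v in self.replicated],
                "tail_probability": self.tail_probability}


def posterior_predictive_replicates(draws: PosteriorDraws, data: DataTable,
                                    n_reps: int, seed: int) -> np.ndarray:
    """Simulate ``n_reps`` datasets at the observed predictor values.

    Each replicate uses the parameters of one posterior draw (draws are
    taken at evenly spaced positions through the flattened chain).  Returns
    an array of shape (n_reps, n_obs).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    from .families import get_link
    from .model_spec import build_design

    model = draws.model
    flat = draws.flat()
    idx = {n: j for j, n in enumerate(draws.parameter_names)}
    X, names = build_design(model, data)
    fixed = model.fixed_parameters()
    beta = np.column_stack([
        flat[:, idx[n]] if n in idx else np.full(flat.shape[0], fixed[n])
        for n in names])
    link = get_link(model.family.link)
    fam = model.family.family_obj
    rng = np.random.default_rng(seed)
    pick = np.linspace(0, flat.shape[0] - 1, n_reps).round().astype(int)

    out = np.empty((n_reps, X.shape[0]))
    for r, s in enumerate(pick):
        mu = link.inverse(X @ beta[s])
        aux = {name: (flat[s, idx[name]] if name in idx else fixed[name])
               for name in fam.aux + fam.fixed_aux}
        out[r] = fam.sample(rng, mu, **aux)
    return out


def ppc_statistic(observed, replicates: np.ndarray, statistic: str) -> PPCResult:
    """Compare an observed summary statistic with its replicated distribution.

    ``tail_probability`` is the two-sided p-value: twice the smaller of the
    fractions of replicates at or beyond the observed value, capped at 1.
    """
    if statistic not in PPC_STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; "
                         f"choose from {sorted(PPC_STATISTICS)}")
    stat = PPC_STATISTICS[statistic]
    y = observed.column(observed.columns[-1]).to_numpy(float) \
        if isinstance(observed, DataTable) else np.asarray(observed, float)
    obs = stat(y)
    rep = np.array([stat(row) for row in np.atleast_2d(replicates)])
    p_hi = float(np.mean(rep >= obs))
    p_lo = float(np.mean(rep <= obs))
    tail = min(1.0, 2.0 * min(p_hi, p_lo))
    return PPCResult(statistic, obs, rep, tail)


# ---------------------------------------------------------------------
# PSIS-LOO
# ---------------------------------------------------------------------

def fit_generalized_pareto(tail_values, threshold: float | None = None
                           ) -> tuple[float, float]:
    """Fit a generalized Pareto to exceedances by the Zhang–Stephens method.

    ``tail_values`` are the raw tail positions; exceedances are measured
    over ``threshold`` (their minimum by default).  Returns the shape
    ``k`` (k=0 for an exponential tail, k~1 for a Cauchy-like tail) and
    the scale ``sigma``.
    """
    x = np.asarray(tail_values, float)
    if x.size < 5:
        raise ValueError("need at least 5 tail values")
    thr = float(np.min(x)) if threshold is None else float(threshold)
    x = np.sort(x - thr)
    x = x[x > 0]
    n = x.size
    if n < 4:
        raise ValueError("degenerate tail: too few distinct exceedances")

    m = 30 + int(np.floor(np.sqrt(n)))
    x_quart = x[int(np.floor(n / 4.0 + 0.5)) - 1]
    j = np.arange(1, m + 1)
    b = 1.0 / x[-1] + (1.0 - np.sqrt(m / (j - 0.5))) / (3.0 * x_quart)
    # profile log-likelihood of theta=b
    k_b = -np.mean(np.log1p(-b[:, None] * x[None, :]), axis=1)
    log_lik = n * (np.log(b / k_b) + k_b - 1.0)
    w = np.exp(log_lik - logsumexp(log_lik))
    b_hat = float(np.sum(w * b))
    k_zs = float(-np.mean(np.log1p(-b_hat * x)))
    sigma = k_zs / b_hat if b_hat != 0 else float(np.mean(x))
    # Zhang–Stephens' shape has the opposite sign of the heavy-tail (PSIS)
    # convention, where an exponential tail gives k=0 and Cauchy-like k=1
    return -k_zs, sigma


def _psis_smooth_column(log_ratios: np.ndarray) -> tuple[np.ndarray, float]:
    """Smooth one observation's log importance ratios; return (log w, k-hat)."""
    s = log_ratios.size
    lw = log_ratios - np.max(log_ratios)
    m = int(min(np.floor(0.2 * s), np.ceil(3.0 * np.sqrt(s))))
    if m < 5:
        return lw, float("-inf")
    order = np.argsort(lw)
    tail_idx = order[-m:]
    cutoff = lw[order[-m - 1]]
    raw_tail = np.exp(lw[tail_idx])
    exceed = raw_tail - np.exp(cutoff)
    if np.allclose(exceed, 0):
        return lw, float("-inf")
    try:
        k, sigma = fit_generalized_pareto(exceed, threshold=0.0)
    except ValueError:
        return lw, float("inf")
    # weak prior pulling k-hat toward 0.5, as in the PSIS recipe
    n_exc = exceed[exceed > 0].size
    k = (n_exc * k + 5.0) / (n_exc + 10.0)
    # replace tail by expected order statistics of the fitted GPD
    probs = (np.arange(1, m + 1) - 0.5) / m
    if abs(k) < 1e-12:
        q = -sigma * np.log1p(-probs)
    else:
        q = sigma / k * ((1.0 - probs) ** (-k) - 1.0)
    smoothed = np.log(np.exp(cutoff) + q)
    # keep tail order, truncate at the raw maximum (= 0 after shift)
    rank = np.argsort(lw[tail_idx])
    new = np.empty(m)
    new[rank] = np.minimum(smoothed, 0.0)
    out = lw.copy()
    out[tail_idx] = new
    return out, float(k)


@dataclass
class LooResult:
    """PSIS-approximated leave-one-out expected log predictive density."""

    elpd_loo: float
    se_elpd: float
    p_loo: float
    pareto_k: np.ndarray
    n_bad_k: int
    elpd_pointwise: np.ndarray = field(default_factory=lambda: np.zeros(0))
    name: str = ""

    def to_dict(self) -> dict:
        return {"elpd_loo": self.elpd_loo, "se_elpd": self.se_elpd,
                "p_loo": self.p_loo, "pareto_k": [float(k) for k in self.pareto_k],
                "n_bad_k": self.n_bad_k, "name": self.name,
                "elpd_pointwise": [float(v) for v in self.elpd_pointwise]}


def psis_loo(loglik: np.ndarray, name: str = "") -> LooResult:
    """PSIS-LOO from a (draw, observation) pointwise log-likelihood matrix."""
    ll = np.asarray(loglik, float)
    if ll.ndim != 2:
        raise ValueError("loglik must be (draws, observations)")
    s, n = ll.shape
    if s < 100:
        raise ValueError("need at least 100 draws for PSIS")
    if not np.all(np.isfinite(ll)):
        raise ValueError("non-finite pointwise log-likelihoods")

    elpd_i = np.empty(n)
    lpd_i = np.empty(n)
    k_hat = np.empty(n)
    for i in range(n):
        lw, k = _psis_smooth_column(-ll[:, i])
        lw = lw - logsumexp(lw)                     # normalize
        elpd_i[i] = logsumexp(lw + ll[:, i])
        lpd_i[i] = logsumexp(ll[:, i]) - np.log(s)  # in-sample lpd
        k_hat[i] = k
    elpd = float(np.sum(elpd_i))
    se = float(np.sqrt(n * np.var(elpd_i, ddof=1))) if n > 1 else 0.0
    p_loo = float(np.sum(lpd_i - elpd_i))
    n_bad = int(np.sum(k_hat > PARETO_K_THRESHOLD))
    return LooResult(elpd, se, p_loo, k_hat, n_bad, elpd_pointwise=elpd_i,
                     name=name)


@dataclass
class ModelComparison:
    models: list[str]
    elpd_diff: dict[str, float]
    se_diff: dict[str, float]
    best: str

    def to_dict(self) -> dict:
        return {"models": list(self.models), "elpd_diff": dict(self.elpd_diff),
                "se_diff": dict(self.se_diff), "best": self.best}


def compare_models(loos: list[LooResult]) -> ModelComparison:
    """Rank models by elpd; differences use paired pointwise contributions."""
    if len(loos) < 2:
        raise ValueError("need at least two models to compare")
    n = loos[0].elpd_pointwise.size
    for lr in loos:
        if lr.elpd_pointwise.size != n or n == 0:
            raise ValueError("models must be fitted to identical observations")
    names = [lr.name or f"model_{i}" for i, lr in enumerate(loos)]
    best_idx = int(np.argmax([lr.elpd_loo for lr in loos]))
    best = loos[best_idx]
    diffs, ses = {}, {}
    for name, lr in zip(names, loos):
        pointwise = lr.elpd_pointwise - best.elpd_pointwise
        diffs[name] = float(np.sum(pointwise))
        ses[name] = float(np.sqrt(n * np.var(pointwise, ddof=1))) if lr is not best else 0.0
    return ModelComparison(names, diffs, ses, names[best_idx])
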