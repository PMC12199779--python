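"""Posterior sampling for GLM specs, with convergence diagnostics.

The sampler is a self-contained adaptive random-walk Metropolis algorithm:
parameters are mapped to an unconstrained space (log transform for
positive auxiliary parameters), all chains move in lockstep through
vectorized likelihood evaluations, and during warmup the proposal
covariance is adapted to the pooled chain history (Haario-style) while a
Robbins–Monro recursion tunes the global step size toward a 30%%
acceptance rate.  Adaptation is frozen at the end of warmup, so the
retained draws come from a valid time-homogeneous Markov chain.  Every
random decision flows from one :class:`numpy.random.Generator`, making
runs bitwise reproducible for a given seed, configuration and data.

Technical validity is certified the usual way: split-chain potential scale
reduction (R-hat), bulk effective sample size, and a divergence count that
is identically zero because random-walk proposals have no divergent
trajectories.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import DataTable
from .families import get_link
from .model_spec import ModelSpec, PriorSpec, build_design, default_priors

__all__ = [
    "SamplerConfig", "PosteriorDraws", "Diagnostics",
    "log_posterior", "fit_model", "compute_rhat", "compute_ess_bulk",
    "pointwise_loglik", "data_digest",
]

RHAT_THRESHOLD = 1.01
ESS_THRESHOLD = 400.0
TARGET_ACCEPT = 0.30


@dataclass
class SamplerConfig:
    """MCMC budget and reproducibility settings."""

    n_chains: int = 4
    n_warmup: int = 1000
    n_draws: int = 2000
    seed: int = 0
    backend: str = "self_contained"

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("need at least 2 chains for convergence diagnostics")
        if self.n_draws < 100:
            raise ValueError("need at least 100 retained draws per chain")
        if self.backend != "self_contained":
            raise ValueError(f"unknown backend {self.backend!r}")

    def to_dict(self) -> dict:
        return {"n_chains": self.n_chains, "n_warmup": self.n_warmup,
                "n_draws": self.n_draws, "seed": self.seed, "backend": self.backend}

    @classmethod
    def from_dict(cls, d: dict) -> "SamplerConfig":
        return cls(**d)


@dataclass
class Diagnostics:
    rhat: dict[str, float]
    ess_bulk: dict[str, float]
    n_divergences: int
    passed: bool

    def to_dict(self) -> dict:
        return {"rhat": dict(self.rhat), "ess_bulk": dict(self.ess_bulk),
                "n_divergences": self.n_divergences, "passed": self.passed}


@dataclass
class PosteriorDraws:
    """Posterior draws indexed (chain, iteration, parameter)."""

    draws: np.ndarray
    parameter_names: list[str]
    model: ModelSpec
    data_digest: str
    seed: int
    config: SamplerConfig | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.draws)):
            raise ValueError("posterior draws contain non-finite values")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    def flat(self) -> np.ndarray:
        """Draws flattened across chains: (chain*iter, parameter)."""
        return self.draws.reshape(-1, self.draws.shape[2])

    def extract(self, parameter: str) -> np.ndarray:
        try:
            j = self.parameter_names.index(parameter)
        except ValueError:
            raise KeyError(f"parameter {parameter!r} not in draws "
                           f"(have {self.parameter_names})") from None
        return self.flat()[:, j]

    def by_chain(self, parameter: str) -> np.ndarray:
        j = self.parameter_names.index(parameter)
        return self.draws[:, :, j]

    def to_dataframe(self) -> pd.DataFrame:
        n_c, n_d, _ = self.draws.shape
        out = pd.DataFrame(self.flat(), columns=self.parameter_names)
        out.insert(0, "iteration", np.tile(np.arange(n_d), n_c))
        out.insert(0, "chain", np.repeat(np.arange(n_c), n_d))
        return out


def data_digest(data: DataTable, columns: Sequence[str]) -> str:
    """Checksum of the columns a model uses, order-sensitive."""
    cols = [c for c in columns if c in data.columns]
    payload = data.df[cols].to_csv(index=False).encode()
    return hashlib.sha256(payload).hexdigest()


# ---------------------------------------------------------------------
# compiled posterior
# ---------------------------------------------------------------------

class CompiledPosterior:
    """Model + data bound into fast batched log-density evaluations."""

    def __init__(self, model: ModelSpec, data: DataTable,
                 priors: Sequence[PriorSpec] | None = None):
        self.model = model.with_levels_from(data)
        self.family = model.family.family_obj
        self.link = get_link(model.family.link)
        used = [model.response] + sorted(
            {v for t in model.terms for v in t.variables})
        if data.n_rows:
            sub = data.df[[c for c in used if c in data.df.columns]]
            if sub.isna().any().any():
                raise ValueError(
                    "data contain missing values in used variables; "
                    "apply complete_cases first")
        self.digest = data_digest(data, used)
        self.y = np.asarray(pd.to_numeric(data.df[model.response]), float) \
            if data.n_rows else np.zeros(0)
        self.X, self.coef_names = build_design(self.model, data)
        self.n_obs = len(self.y)

        prior_list = list(priors if priors is not None else model.priors)
        by_param = {p.parameter: p for p in prior_list}
        self.fixed = self.model.fixed_parameters()

        self.free_names: list[str] = []
        self.free_priors: list[PriorSpec] = []
        self.free_positive: list[bool] = []
        fam_aux = list(self.family.aux)
        for name in self.coef_names + fam_aux:
            if name in self.fixed:
                continue
            prior = by_param.get(name)
            if prior is None:
                raise ValueError(f"no prior given for free parameter {name!r}")
            if prior.distribution == "point":
                self.fixed[name] = float(prior.hyperparams["value"])
                continue
            self.free_names.append(name)
            self.free_priors.append(prior)
            self.free_positive.append(name in fam_aux)
        self.positive = np.array(self.free_positive, bool)
        self.aux_names = fam_aux + list(self.family.fixed_aux)

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    # --- transforms ----------------------------------------------------
    def to_unconstrained(self, theta: np.ndarray) -> np.ndarray:
        z = np.array(theta, float, copy=True)
        z[..., self.positive] = np.log(z[..., self.positive])
        return z

    def to_constrained(self, z: np.ndarray) -> np.ndarray:
        theta = np.array(z, float, copy=True)
        theta[..., self.positive] = np.exp(theta[..., self.positive])
        return theta

    # --- densities ------------------------------------------------------
    def _split(self, theta: np.ndarray) -> tuple[np.ndarray, dict]:
        """theta (B, n_free) -> coefficient matrix (B, p) and aux dict of (B,)."""
        B = theta.shape[0]
        coef = np.empty((B, len(self.coef_names)))
        aux: dict[str, np.ndarray] = {}
        free_idx = {n: j for j, n in enumerate(self.free_names)}
        for j, name in enumerate(self.coef_names):
            coef[:, j] = theta[:, free_idx[name]] if name in free_idx \
                else self.fixed[name]
        for name in self.aux_names:
            aux[name] = theta[:, free_idx[name]] if name in free_idx \
                else np.full(B, self.fixed[name])
        return coef, aux

    def pointwise_loglik(self, theta: np.ndarray) -> np.ndarray:
        """theta (B, n_free) -> loglik matrix (B, n_obs)."""
        theta = np.atleast_2d(theta)
        coef, aux = self._split(theta)
        if self.n_obs == 0:
            return np.zeros((theta.shape[0], 0))
        eta = self.X @ coef.T                     # (n_obs, B)
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            mu = self.link.inverse(eta)
            ll = self.family.loglik(self.y[:, None], mu, **aux)
        return np.nan_to_num(ll, nan=-np.inf, posinf=-np.inf).T

    def log_prior(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        lp = np.zeros(theta.shape[0])
        for j, prior in enumerate(self.free_priors):
            with np.errstate(divide="ignore", invalid="ignore"):
                lp += prior.logpdf(theta[:, j])
        bad = self.positive[None, :] & (theta <= 0)
        lp[np.any(bad, axis=1)] = -np.inf
        return lp

    def log_posterior_unconstrained(self, z: np.ndarray) -> np.ndarray:
        """Log posterior + log-Jacobian of the transform, batched over rows."""
        z = np.atleast_2d(z)
        theta = self.to_constrained(z)
        lp = self.log_prior(theta) + self.pointwise_loglik(theta).sum(axis=1)
        jac = z[:, self.positive].sum(axis=1) if self.positive.any() else 0.0
        out = lp + jac
        return np.where(np.isnan(out), -np.inf, out)


def log_posterior(model: ModelSpec, data: DataTable,
                  parameters: Mapping[str, float]) -> float:
    """Sum of pointwise log-likelihoods plus log-priors at a parameter point.

    Parameters outside their support return ``-inf`` by contract.
    """
    cp = CompiledPosterior(model, data)
    theta = np.empty(cp.n_free)
    for j, name in enumerate(cp.free_names):
        if name not in parameters:
            raise KeyError(f"parameter {name!r} missing")
        theta[j] = parameters[name]
    if np.any(theta[cp.positive] <= 0):
        return -np.inf
    lp = float(cp.log_prior(theta[None, :])[0] +
               cp.pointwise_loglik(theta[None, :]).sum())
    return lp


# ---------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------

def _initial_points(cp: CompiledPosterior, rng: np.random.Generator,
                    n_chains: int) -> np.ndarray:
    """Prior draws shrunk halfway to the prior median, retried on -inf."""
    z = np.empty((n_chains, cp.n_free))
    for c in range(n_chains):
        ok = False
        for _ in range(10):
            theta = np.array([
                p.median() + 0.5 * (p.sample(rng) - p.median())
                for p in cp.free_priors])
            theta[cp.positive] = np.maximum(theta[cp.positive], 1e-6)
            zc = cp.to_unconstrained(theta)
            if np.isfinite(cp.log_posterior_unconstrained(zc[None, :])[0]):
                z[c] = zc
                ok = True
                break
        if not ok:
            raise RuntimeError(
                "could not find a finite log-posterior initialization "
                "after 10 attempts")
    return z


def fit_model(model: ModelSpec, data: DataTable, config: SamplerConfig
              ) -> tuple[PosteriorDraws, Diagnostics]:
    """Sample the posterior of ``model`` given ``data``.

    Priors missing from the model are filled in with :func:`default_priors`.
    Returns the draws (constrained scale) and convergence diagnostics
    computed on them.
    """
    priors = list(model.priors)
    have = {p.parameter for p in priors}
    # fill in autoscaled defaults for parameters without explicit priors
    needed = set(model.parameter_names()) - set(model.fixed_parameters()) - have
    if needed:
        for p in default_priors(model.with_levels_from(data), data):
            if p.parameter in needed:
                priors.append(p)
    cp = CompiledPosterior(model, data, priors=priors)
    if cp.n_free == 0:
        raise ValueError("model has no free parameters to sample")

    rng = np.random.default_rng(config.seed)
    d = cp.n_free
    B = config.n_chains
    z = _initial_points(cp, rng, B)
    lp = cp.log_posterior_unconstrained(z)

    chol = np.eye(d)
    log_s = np.log(0.5 * 2.38 / np.sqrt(d))
    # pooled running moments for covariance adaptation
    count, mean, m2 = 0, np.zeros(d), np.zeros((d, d))

    def step(z, lp, scale, chol):
        eps = rng.standard_normal((B, d))
        prop = z + scale * (eps @ chol.T)
        lp_prop = cp.log_posterior_unconstrained(prop)
        logu = np.log(rng.random(B))
        acc = logu < (lp_prop - lp)
        z = np.where(acc[:, None], prop, z)
        lp = np.where(acc, lp_prop, lp)
        return z, lp, acc

    for t in range(config.n_warmup):
        z, lp, acc = step(z, lp, np.exp(log_s), chol)
        gamma = (t + 1) ** -0.6
        log_s += gamma * (acc.mean() - TARGET_ACCEPT)
        # pooled chunk update of running moments (Chan et al.)
        bmean = z.mean(axis=0)
        delta = bmean - mean
        tot = count + B
        zc = z - bmean
        m2 += zc.T @ zc + np.outer(delta, delta) * (count * B / tot)
        mean += delta * (B / tot)
        count = tot
        if count > max(50, 5 * d) and (t + 1) % 50 == 0:
            cov = m2 / (count - 1) + 1e-8 * np.eye(d)
            chol = np.linalg.cholesky(cov)

    scale = np.exp(log_s)
    draws_u = np.empty((B, config.n_draws, d))
    for t in range(config.n_draws):
        z, lp, _ = step(z, lp, scale, chol)
        draws_u[:, t, :] = z

    draws = cp.to_constrained(draws_u)
    post = PosteriorDraws(draws=draws, parameter_names=list(cp.free_names),
                          model=cp.model, data_digest=cp.digest,
                          seed=config.seed, config=config)
    diag = compute_diagnostics(post)
    return post, diag


# ---------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------

def _split_chains(x: np.ndarray) -> np.ndarray:
    n = x.shape[1] // 2
    return np.concatenate([x[:, :n], x[:, n:2 * n]], axis=0)


def compute_rhat(x: "np.ndarray | PosteriorDraws") -> "float | dict[str, float]":
    """Split-chain potential scale reduction factor.

    Accepts a (chain, draw) array for one parameter, or a
    :class:`PosteriorDraws` (returns a dict keyed by parameter).  Constant
    parameters have no defined R-hat and are reported as NaN.
    """
    if isinstance(x, PosteriorDraws):
        return {p: compute_rhat(x.by_chain(p)) for p in x.parameter_names}
    x = np.asarray(x, float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 4:
        raise ValueError("need (chains, draws) with >=2 chains and >=4 draws")
    halves = _split_chains(x)
    n = halves.shape[1]
    w = halves.var(axis=1, ddof=1).mean()
    b = n * halves.mean(axis=1).var(ddof=1)
    if w == 0:
        return float("nan")
    var_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(var_hat / w))


def compute_ess_bulk(x: np.ndarray) -> float:
    """Bulk effective sample size (delegated to arviz)."""
    import arviz as az
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.ess(np.asarray(x, float), method="bulk"))


def compute_diagnostics(draws: PosteriorDraws) -> Diagnostics:
    rhat = {}
    ess = {}
    for p in draws.parameter_names:
        arr = draws.by_chain(p)
        rhat[p] = compute_rhat(arr)
        ess[p] = compute_ess_bulk(arr)
    rvals = np.array(list(rhat.values()))
    evals = np.array(list(ess.values()))
    passed = (np.all(np.isfinite(rvals)) and np.max(rvals) <= RHAT_THRESHOLD
              and np.min(evals) >= ESS_THRESHOLD)
    return Diagnostics(rhat=rhat, ess_bulk=ess, n_divergences=0, passed=bool(passed))


def pointwise_loglik(draws: PosteriorDraws, data: DataTable) -> np.ndarray:
    """Log-likelihood of every observation under every posterior draw.

    Shape (n_total_draws, n_obs); rows sum to the total log-likelihood of
    the corresponding draw.  The data must be the table the model was
    fitted to (checked via digest).
    """
    cp = CompiledPosterior(draws.model, data,
                           priors=[PriorSpec(n, "flat") for n in draws.parameter_names])
    if cp.digest != draws.data_digest:
        raise ValueError("data do not match the table these draws were fitted to")
    theta = draws.flat()
    order = [draws.parameter_names.index(n) for n in cp.free_names]
    return cp.pointwise_loglik(theta[:, order])
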