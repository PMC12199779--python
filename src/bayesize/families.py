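"""Noise families and link functions for generalized linear models.

Every family is parameterized by the mean of the response (``mu``) plus the
auxiliary parameters the family needs (``sigma`` for the normal, the
dispersion ``phi`` for the negative binomial, ...).  The one exception is
the lognormal, whose location is the mean of ``log y`` (so the log link maps
the linear predictor to the *median* of the response, not its mean).

Log-likelihoods are written directly in terms of ``scipy.special``
primitives so that they broadcast over batches of parameter vectors: ``y``
enters with shape ``(n_obs, 1)``, ``mu`` with ``(n_obs, n_batch)`` and each
auxiliary parameter with ``(n_batch,)``.  The unit tests cross-check each
density against the corresponding ``scipy.stats`` distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.special import expit, gammaln, betaln, ndtr, ndtri

__all__ = ["Link", "Family", "LINKS", "FAMILIES", "get_family", "get_link"]

_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class Link:
    """A link function g and its inverse, mapping mean scale <-> linear scale."""

    name: str
    forward: Callable[[np.ndarray], np.ndarray]   # mean -> eta
    inverse: Callable[[np.ndarray], np.ndarray]   # eta -> mean


LINKS: dict[str, Link] = {
    "identity": Link("identity", lambda m: np.asarray(m, float), lambda e: np.asarray(e, float)),
    "log": Link("log", np.log, np.exp),
    "logit": Link("logit", lambda m: np.log(m / (1.0 - m)), expit),
    "probit": Link("probit", ndtri, ndtr),
}


def get_link(name: str) -> Link:
    try:
        return LINKS[name]
    except KeyError:
        raise ValueError(f"unknown link function {name!r}") from None


@dataclass(frozen=True)
class Family:
    """A noise family: support, links, auxiliary parameters, density, sampler.

    ``aux`` are the free auxiliary parameters (sampled unless given a point
    prior); ``fixed_aux`` must be supplied as known constants (the binomial
    trial count).  ``response_kinds`` lists the variable kinds the family can
    model; ``mean_interval`` is the support of the mean.
    """

    name: str
    links: tuple[str, ...]
    default_link: str
    aux: tuple[str, ...]
    fixed_aux: tuple[str, ...]
    response_kinds: tuple[str, ...]
    mean_interval: tuple[float, float]
    discrete: bool
    loglik: Callable[..., np.ndarray]        # (y, mu, **aux) -> elementwise loglik
    sample: Callable[..., np.ndarray]        # (rng, mu, **aux) -> draws
    variance: Callable[..., np.ndarray]      # (mu, **aux) -> sampling variance

    @property
    def aux_names(self) -> tuple[str, ...]:
        return self.aux + self.fixed_aux


def _normal_ll(y, mu, sigma):
    return -0.5 * ((y - mu) / sigma) ** 2 - np.log(sigma) - _HALF_LOG_2PI


def _lognormal_ll(y, mu, sigma):
    # mu is the mean of log(y)
    logy = np.log(y)
    return _normal_ll(logy, mu, sigma) - logy


def _poisson_ll(y, mu):
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = y * np.log(mu) - mu - gammaln(y + 1.0)
    return np.where((mu == 0) & (y == 0), -gammaln(y + 1.0), ll)


def _negbinom_ll(y, mu, phi):
    # mean/dispersion parameterization, Var = mu + mu^2/phi
    with np.errstate(divide="ignore", invalid="ignore"):
        return (
            gammaln(y + phi) - gammaln(phi) - gammaln(y + 1.0)
            + phi * np.log(phi / (phi + mu))
            + y * np.log(mu / (phi + mu))
        )


def _gamma_ll(y, mu, shape):
    rate = shape / mu
    return shape * np.log(rate) - gammaln(shape) + (shape - 1.0) * np.log(y) - rate * y


def _exponential_ll(y, mu):
    return -np.log(mu) - y / mu


def _invgauss_ll(y, mu, lam):
    return 0.5 * (np.log(lam) - np.log(2.0 * np.pi * y**3)) - lam * (y - mu) ** 2 / (2.0 * mu**2 * y)


def _binomial_ll(y, p, trials):
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = (
            gammaln(trials + 1.0) - gammaln(y + 1.0) - gammaln(trials - y + 1.0)
            + y * np.log(p) + (trials - y) * np.log1p(-p)
        )
    # 0*log(0) limits
    ll = np.where((y == 0) & (p == 0), 0.0, ll)
    ll = np.where((y == trials) & (p == 1), 0.0, ll)
    return ll


def _beta_ll(y, mu, kappa):
    a = mu * kappa
    b = (1.0 - mu) * kappa
    return (a - 1.0) * np.log(y) + (b - 1.0) * np.log1p(-y) - betaln(a, b)


FAMILIES: dict[str, Family] = {
    "normal": Family(
        "normal", ("identity",), "identity", ("sigma",), (), ("continuous",),
        (-np.inf, np.inf), False,
        _normal_ll,
        lambda rng, mu, sigma: rng.normal(mu, sigma),
        lambda mu, sigma: np.broadcast_to(np.asarray(sigma, float) ** 2, np.shape(mu)).copy(),
    ),
    "lognormal": Family(
        "lognormal", ("log",), "log", ("sigma",), (), ("continuous",),
        (0.0, np.inf), False,
        _lognormal_ll,
        lambda rng, mu, sigma: rng.lognormal(np.log(mu), sigma),
        lambda mu, sigma: (np.exp(sigma**2) - 1.0) * np.exp(2.0 * np.log(mu) + sigma**2),
    ),
    "poisson": Family(
        "poisson", ("log",), "log", (), (), ("count",),
        (0.0, np.inf), True,
        _poisson_ll,
        lambda rng, mu: rng.poisson(mu),
        lambda mu: np.asarray(mu, float),
    ),
    "negative_binomial": Family(
        "negative_binomial", ("log",), "log", ("phi",), (), ("count",),
        (0.0, np.inf), True,
        _negbinom_ll,
        lambda rng, mu, phi: rng.negative_binomial(phi, phi / (phi + mu)),
        lambda mu, phi: mu + mu**2 / phi,
    ),
    "gamma": Family(
        "gamma", ("log",), "log", ("shape",), (), ("continuous",),
        (0.0, np.inf), False,
        _gamma_ll,
        lambda rng, mu, shape: rng.gamma(shape, mu / shape),
        lambda mu, shape: mu**2 / shape,
    ),
    "exponential": Family(
        "exponential", ("log",), "log", (), (), ("continuous",),
        (0.0, np.inf), False,
        _exponential_ll,
        lambda rng, mu: rng.exponential(mu),
        lambda mu: np.asarray(mu, float) ** 2,
    ),
    "inverse_gaussian": Family(
        "inverse_gaussian", ("log",), "log", ("lam",), (), ("continuous",),
        (0.0, np.inf), False,
        _invgauss_ll,
        lambda rng, mu, lam: rng.wald(mu, lam),
        lambda mu, lam: mu**3 / lam,
    ),
    "binomial": Family(
        "binomial", ("logit", "probit"), "logit", (), ("trials",),
        ("count", "binary", "proportion"), (0.0, 1.0), True,
        _binomial_ll,
        lambda rng, mu, trials: rng.binomial(int(trials), mu),
        lambda mu, trials: trials * mu * (1.0 - mu),
    ),
    "beta": Family(
        "beta", ("logit", "probit"), "logit", ("kappa",), (), ("proportion",),
        (0.0, 1.0), False,
        _beta_ll,
        lambda rng, mu, kappa: rng.beta(mu * kappa, (1.0 - mu) * kappa),
        lambda mu, kappa: mu * (1.0 - mu) / (1.0 + kappa),
    ),
}


def get_family(name: str) -> Family:
    try:
        return FAMILIES[name]
    except KeyError:
        raise ValueError(
            f"unknown family {name!r}; choose from {sorted(FAMILIES)}"
        ) from None
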