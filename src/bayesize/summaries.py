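"""Posterior summaries: credible intervals, pairwise effects, predictions.

Intervals come in two flavours.  The equal-tailed interval (ETI) cuts equal
probability from both tails using type-7 (linearly interpolated) sample
quantiles.  The highest density interval (HDI) is the shortest contiguous
window of sorted draws containing the requested mass; ties are broken
toward the smallest lower bound, making the estimator deterministic.

Effects between levels of a categorical predictor are reported on the
scale the link implies: differences for the identity link, multipliers
(ratios of means) for the log link, log-odds ratios and odds ratios for
the logit link.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .families import get_link
from .inference import PosteriorDraws
from .model_spec import build_design

__all__ = [
    "IntervalSummary", "EffectEntry", "EffectMatrix", "PredictionResult",
    "eti", "hdi", "summarize_parameters", "effect_matrix", "predict_outcomes",
    "SCALE_BY_LINK",
]

DEFAULT_MASS = 0.95
DEFAULT_METHOD = "hdi"

#: Effect scale implied by each link function.
SCALE_BY_LINK = {"identity": ("difference",),
                 "log": ("multiplier",),
                 "logit": ("log_odds_ratio", "odds_ratio"),
                 "probit": ("difference",)}


@dataclass
class IntervalSummary:
    parameter: str
    point: float              # posterior median
    lower: float
    upper: float
    mass: float
    method: str

    def width(self) -> float:
        return self.upper - self.lower

    def to_dict(self) -> dict:
        return {"parameter": self.parameter, "point": self.point,
                "lower": self.lower, "upper": self.upper,
                "mass": self.mass, "method": self.method}


def eti(values, mass: float) -> tuple[float, float]:
    """Equal-tailed interval via type-7 quantiles at (1-mass)/2 and (1+mass)/2."""
    values = np.asarray(values, float)
    if not 0 < mass < 1:
        raise ValueError("mass must lie strictly inside (0, 1)")
    if values.size < 2:
        raise ValueError("need at least two values")
    lo, hi = np.quantile(values, [(1 - mass) / 2, (1 + mass) / 2])
    return float(lo), float(hi)


def hdi(values, mass: float) -> tuple[float, float]:
    """Shortest contiguous interval of sorted draws containing ceil(mass*n).

    Among equally short windows the one with the smallest lower bound wins.
    """
    values = np.asarray(values, float)
    if not 0 < mass < 1:
        raise ValueError("mass must lie strictly inside (0, 1)")
    n = values.size
    if n < 2:
        raise ValueError("need at least two values")
    srt = np.sort(values)
    m = int(np.ceil(mass * n))
    m = min(max(m, 2), n)
    widths = srt[m - 1:] - srt[: n - m + 1]
    i = int(np.argmin(widths))          # argmin takes the first (smallest lower)
    return float(srt[i]), float(srt[i + m - 1])


def _interval(values, mass: float, method: str) -> tuple[float, float]:
    if method == "eti":
        return eti(values, mass)
    if method == "hdi":
        return hdi(values, mass)
    raise ValueError(f"unknown interval method {method!r}")


def _summary(name: str, values, mass: float, method: str) -> IntervalSummary:
    lo, hi = _interval(values, mass, method)
    return IntervalSummary(name, float(np.median(values)), lo, hi, mass, method)


def summarize_parameters(draws: PosteriorDraws, mass: float = DEFAULT_MASS,
                         method: str = DEFAULT_METHOD) -> list[IntervalSummary]:
    """One interval summary per parameter, draws flattened across chains."""
    return [_summary(p, draws.extract(p), mass, method)
            for p in draws.parameter_names]


@dataclass
class EffectEntry:
    """Per-draw effect of ``level_a`` relative to ``level_b`` on one scale."""

    level_a: str
    level_b: str
    scale: str
    draws: np.ndarray
    summary: IntervalSummary

    def reversed(self) -> "EffectEntry":
        if self.scale in ("multiplier", "odds_ratio"):
            rev = 1.0 / self.draws
        else:
            rev = -self.draws
        name = f"{self.scale}({self.level_b} vs {self.level_a})"
        return EffectEntry(self.level_b, self.level_a, self.scale, rev,
                           _summary(name, rev, self.summary.mass, self.summary.method))


@dataclass
class EffectMatrix:
    """All pairwise level effects of one categorical predictor."""

    predictor: str
    levels: list[str]
    entries: dict[tuple[str, str], list[EffectEntry]]

    def entry(self, a: str, b: str, scale: str | None = None) -> EffectEntry:
        key = (a, b) if (a, b) in self.entries else (b, a)
        if key not in self.entries:
            raise KeyError(f"no entry for pair ({a}, {b})")
        options = self.entries[key]
        ent = options[0] if scale is None else \
            next(e for e in options if e.scale == scale)
        return ent if key == (a, b) else ent.reversed()

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for (a, b), ents in self.entries.items():
            for e in ents:
                rows.append({"level_a": a, "level_b": b, "scale": e.scale,
                             "point": e.summary.point, "lower": e.summary.lower,
                             "upper": e.summary.upper, "mass": e.summary.mass,
                             "method": e.summary.method})
        return pd.DataFrame(rows)


def _level_eta_contrast(draws: PosteriorDraws, predictor: str,
                        level_a: str, level_b: str) -> np.ndarray:
    """Per-draw eta(level_a) - eta(level_b), other predictors held fixed.

    With dummy coding the contrast is a difference of the predictor's own
    coefficients (the reference level contributing zero), so it does not
    depend on where the remaining predictors sit as long as the model has
    no interaction involving ``predictor``.
    """
    def coef(level: str) -> np.ndarray:
        name = f"{predictor}[{level}]"
        if name in draws.parameter_names:
            return draws.extract(name)
        return np.zeros(draws.flat().shape[0])     # reference level

    return coef(level_a) - coef(level_b)


def effect_matrix(draws: PosteriorDraws, predictor: str,
                  mass: float = DEFAULT_MASS, method: str = DEFAULT_METHOD
                  ) -> EffectMatrix:
    """Pairwise effects between all levels of a categorical predictor.

    Entries are stored once per unordered pair (lexicographically smaller
    level first); the reverse orientation is derived on demand.
    """
    model = draws.model
    levels = model.categorical_levels.get(predictor)
    if levels is None:
        raise ValueError(f"{predictor!r} is not a categorical predictor "
                         "of the fitted model")
    for term in model.terms:
        if term.kind == "interaction" and predictor in term.variables:
            raise ValueError(
                f"pairwise effects for {predictor!r} are not defined when it "
                "appears in an interaction term")
    scales = SCALE_BY_LINK[model.family.link]
    ordered = sorted(levels)
    entries: dict[tuple[str, str], list[EffectEntry]] = {}
    for i, a in enumerate(ordered):
        for b in ordered[i + 1:]:
            delta = _level_eta_contrast(draws, predictor, a, b)
            ents = []
            for scale in scales:
                if scale in ("multiplier", "odds_ratio"):
                    vals = np.exp(delta)
                else:
                    vals = delta
                ents.append(EffectEntry(
                    a, b, scale, vals,
                    _summary(f"{scale}({a} vs {b})", vals, mass, method)))
            entries[(a, b)] = ents
    return EffectMatrix(predictor, ordered, entries)


@dataclass
class PredictionResult:
    inputs: dict
    mean_draws: np.ndarray
    predictive_draws: np.ndarray
    mean_summary: IntervalSummary
    predictive_summary: IntervalSummary


def predict_outcomes(draws: PosteriorDraws, inputs: Mapping[str, object],
                     seed: int, mass: float = DEFAULT_MASS,
                     method: str = DEFAULT_METHOD) -> PredictionResult:
    """Posterior mean and posterior predictive draws at one predictor setting.

    ``mean_draws`` is inverse-link(eta) per posterior draw; each
    ``predictive_draw`` adds one sample of the family's noise on top.
    """
    model = draws.model
    needed = {v for t in model.terms for v in t.variables}
    missing = needed - set(inputs)
    if missing:
        raise KeyError(f"inputs missing predictors: {sorted(missing)}")
    X, names = build_design(model, pd.DataFrame([dict(inputs)]))
    flat = draws.flat()
    idx = {n: j for j, n in enumerate(draws.parameter_names)}
    beta = np.column_stack([
        flat[:, idx[n]] if n in idx
        else np.full(flat.shape[0], model.fixed_parameters()[n])
        for n in names]) if names else np.zeros((flat.shape[0], 0))
    eta = beta @ X[0]
    link = get_link(model.family.link)
    mu = link.inverse(eta)

    fam = model.family.family_obj
    fixed = model.fixed_parameters()
    aux = {}
    for name in fam.aux + fam.fixed_aux:
        aux[name] = flat[:, idx[name]] if name in idx else \
            np.full(flat.shape[0], fixed[name])
    rng = np.random.default_rng(seed)
    if fam.name == "binomial":
        pred = rng.binomial(np.asarray(aux["trials"], int), mu)
    else:
        pred = fam.sample(rng, mu, **aux)
    pred = np.asarray(pred, float)

    return PredictionResult(
        inputs=dict(inputs), mean_draws=mu, predictive_draws=pred,
        mean_summary=_summary("mean", mu, mass, method),
        predictive_summary=_summary("predictive", pred, mass, method))
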