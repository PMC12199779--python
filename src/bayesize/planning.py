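"""Simulation-based sample-size determination (Bayesian assurance).

The planning loop pairs two models that share one GLM structure: a
*data-generation* model whose parameters are pinned to assumed ground
truth, and an *inference* model that will later analyse the real
experiment.  For each candidate sample size, many datasets are simulated
from the ground truth, the inference model is fitted to each, and a
user-defined goal — a maximum credible-interval width (precision) or the
exclusion of a region of practical equivalence (ROPE) — is tested on each
posterior.  The fraction of successes estimates the power at that size,
and the recommended sample size is the smallest candidate whose power
reaches the target.

The module also ships the conventional comparator: the two-sample power
t-test sample size from a noncentral-t power equation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil, sqrt

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data_model import DataTable
from .families import get_link
from .inference import PosteriorDraws, SamplerConfig, fit_model
from .model_spec import FamilySpec, LinearTerm, ModelSpec, PriorSpec, build_design
from .summaries import _interval, effect_matrix

__all__ = [
    "Goal", "PlanningConfig", "PowerEstimate", "PlanningResult", "TTestParams",
    "simulate_dataset", "evaluate_goal", "estimate_power_at_n",
    "find_min_sample_size", "t_test_sample_size", "wilson_interval",
    "two_group_nb_scenario",
]


@dataclass
class Goal:
    """A decidable predicate on a posterior.

    ``precision``: the credible interval of the target parameter must be no
    wider than ``max_width``.  ``rope_exclusion``: the interval must lie
    entirely outside [rope_lower, rope_upper].
    """

    kind: str
    target_parameter: str
    interval_mass: float = 0.95
    interval_method: str = "hdi"
    max_width: float | None = None
    rope_lower: float | None = None
    rope_upper: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("precision", "rope_exclusion"):
            raise ValueError(f"unknown goal kind {self.kind!r}")
        if self.kind == "precision":
            if self.max_width is None or self.max_width < 0:
                raise ValueError("precision goal needs max_width >= 0")
        else:
            if self.rope_lower is None or self.rope_upper is None \
                    or not self.rope_lower < self.rope_upper:
                raise ValueError("rope goal needs rope_lower < rope_upper")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("kind", "target_parameter", "interval_mass", "interval_method",
                 "max_width", "rope_lower", "rope_upper")}

    @classmethod
    def from_dict(cls, d: dict) -> "Goal":
        return cls(**{k: v for k, v in d.items() if v is not None or k in
                      ("max_width", "rope_lower", "rope_upper")})


@dataclass
class PlanningConfig:
    n_candidates: list[int]
    n_replicates: int = 200
    power_target: float = 0.8
    seed: int = 0
    sampler: SamplerConfig = field(default_factory=lambda: SamplerConfig(
        n_chains=2, n_warmup=400, n_draws=600, seed=0))

    def __post_init__(self) -> None:
        self.n_candidates = [int(n) for n in self.n_candidates]
        if not self.n_candidates:
            raise ValueError("candidate list is empty")
        if any(b <= a for a, b in zip(self.n_candidates, self.n_candidates[1:])):
            raise ValueError("candidates must be strictly increasing")
        if self.n_replicates < 20:
            raise ValueError("need >= 20 replicates for a recommendation")
        if not 0 < self.power_target < 1:
            raise ValueError("power_target must lie in (0, 1)")

    def to_dict(self) -> dict:
        return {"n_candidates": list(self.n_candidates),
                "n_replicates": self.n_replicates,
                "power_target": self.power_target, "seed": self.seed,
                "sampler": self.sampler.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "PlanningConfig":
        d = dict(d)
        d["sampler"] = SamplerConfig.from_dict(d["sampler"])
        return cls(**d)


@dataclass
class PowerEstimate:
    n: int
    n_success: int
    n_replicates: int
    power: float
    ci_lower: float
    ci_upper: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("n", "n_success", "n_replicates", "power", "ci_lower", "ci_upper")}


@dataclass
class PlanningResult:
    estimates: list[PowerEstimate]
    recommended_n: int | None
    goal: Goal
    config: PlanningConfig
    n_is_per_group: bool = True

    def power_curve(self) -> pd.DataFrame:
        return pd.DataFrame([e.to_dict() for e in sorted(self.estimates,
                                                         key=lambda e: e.n)])

    def to_dict(self) -> dict:
        return {"estimates": [e.to_dict() for e in self.estimates],
                "recommended_n": self.recommended_n,
                "goal": self.goal.to_dict(), "config": self.config.to_dict(),
                "n_is_per_group": self.n_is_per_group}


def wilson_interval(successes: int, trials: int, level: float = 0.95
                    ) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion."""
    z = stats.norm.ppf(0.5 + level / 2)
    p = successes / trials
    denom = 1 + z**2 / trials
    center = (p + z**2 / (2 * trials)) / denom
    half = z * sqrt(p * (1 - p) / trials + z**2 / (4 * trials**2)) / denom
    return max(0.0, center - half), min(1.0, center + half)


# ---------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------

def _design_frame(dg_model: ModelSpec, design) -> pd.DataFrame:
    """Expand a design (total n, or per-group sizes) into predictor rows."""
    cats = [v for v in dg_model.categorical_levels
            if any(v in t.variables for t in dg_model.terms)]
    if isinstance(design, pd.DataFrame):
        return design.reset_index(drop=True)
    if isinstance(design, int):
        if cats:
            raise ValueError("model has categorical predictors; give per-group sizes")
        return pd.DataFrame(index=range(design))
    if isinstance(design, dict):
        if len(cats) != 1:
            raise ValueError("per-group design needs exactly one categorical predictor")
        var = cats[0]
        known = set(dg_model.categorical_levels[var])
        unknown = set(design) - known
        if unknown:
            raise ValueError(f"unknown level(s) {sorted(unknown)} for {var!r}")
        rows = [{var: level} for level, size in sorted(design.items())
                for _ in range(int(size))]
        return pd.DataFrame(rows, columns=[var])
    raise TypeError("design must be an int, a {level: size} dict, or a DataFrame")


def simulate_dataset(dg_model: ModelSpec, design, seed: int) -> DataTable:
    """Simulate responses from a fully specified data-generation model.

    ``design`` gives the predictor layout: a total row count for
    intercept-only models, ``{level: size}`` for one categorical predictor,
    or a full predictor DataFrame.  Deterministic given the seed.
    """
    if dg_model.role != "data_generation":
        raise ValueError("simulate_dataset needs a role=data_generation model")
    frame = _design_frame(dg_model, design)
    params = dg_model.fixed_parameters()
    fam = dg_model.family.family_obj
    link = get_link(dg_model.family.link)
    rng = np.random.default_rng(seed)

    if len(frame) == 0:
        df = frame.copy()
        df[dg_model.response] = pd.Series(dtype=float)
        return DataTable(df, provenance="simulated")
    X, names = build_design(dg_model, frame)
    beta = np.array([params[n] for n in names])
    mu = link.inverse(X @ beta)
    aux = {name: params[name] for name in fam.aux + fam.fixed_aux}
    y = fam.sample(rng, mu, **aux)
    df = frame.copy()
    df[dg_model.response] = np.asarray(y, float)
    return DataTable(df, provenance="simulated")


# ---------------------------------------------------------------------
# goals and power
# ---------------------------------------------------------------------

def _target_draws(draws: PosteriorDraws, goal: Goal) -> np.ndarray:
    name = goal.target_parameter
    if name in draws.parameter_names:
        return draws.extract(name)
    # derived effect entries: "predictor:levelA/levelB" on the link's scale
    if ":" in name and "/" in name:
        pred, pair = name.split(":", 1)
        a, b = pair.split("/", 1)
        mat = effect_matrix(draws, pred, goal.interval_mass, goal.interval_method)
        return mat.entry(a, b).draws
    raise KeyError(f"target parameter {name!r} not found in posterior draws")


def evaluate_goal(draws: PosteriorDraws, goal: Goal) -> bool:
    """Decide goal achievement on one posterior."""
    values = _target_draws(draws, goal)
    lo, hi = _interval(values, goal.interval_mass, goal.interval_method)
    if goal.kind == "precision":
        return bool(hi - lo <= goal.max_width)
    return bool(hi < goal.rope_lower or lo > goal.rope_upper)


def _replicate_seed(seed: int, r: int) -> int:
    return int(np.random.SeedSequence([seed, r]).generate_state(1)[0] % (2**31))


def estimate_power_at_n(dg_model: ModelSpec, inf_model: ModelSpec, goal: Goal,
                        n: int, n_replicates: int, seed: int,
                        sampler: SamplerConfig | None = None,
                        ci_level: float = 0.95) -> PowerEstimate:
    """Power at one candidate size via simulate -> fit -> evaluate cycles.

    ``n`` is the per-group size when the data-generation model has a
    categorical predictor, otherwise the total size.  Replicate ``r`` uses
    a seed derived deterministically from (seed, r); a replicate whose fit
    fails beyond one retry counts as a failure rather than aborting.
    """
    sampler = sampler or SamplerConfig(n_chains=2, n_warmup=400, n_draws=600, seed=0)
    cats = [v for v in dg_model.categorical_levels
            if any(v in t.variables for t in dg_model.terms)]
    design = {lv: n for lv in dg_model.categorical_levels[cats[0]]} if cats else n

    successes = 0
    for r in range(n_replicates):
        rep_seed = _replicate_seed(seed, r)
        data = simulate_dataset(dg_model, design, seed=rep_seed)
        ok = False
        for attempt in range(2):
            try:
                cfg = SamplerConfig(sampler.n_chains, sampler.n_warmup,
                                    sampler.n_draws,
                                    seed=rep_seed + attempt,
                                    backend=sampler.backend)
                draws, _ = fit_model(inf_model, data, cfg)
                ok = evaluate_goal(draws, goal)
                break
            except (RuntimeError, ValueError, np.linalg.LinAlgError):
                continue
        successes += int(ok)
    lo, hi = wilson_interval(successes, n_replicates, ci_level)
    return PowerEstimate(n=int(n), n_success=successes,
                         n_replicates=n_replicates,
                         power=successes / n_replicates,
                         ci_lower=lo, ci_upper=hi)


def find_min_sample_size(dg_model: ModelSpec, inf_model: ModelSpec, goal: Goal,
                         config: PlanningConfig) -> PlanningResult:
    """Home in on the smallest candidate size meeting the power target.

    Power is assumed approximately monotone in n, so the sorted candidate
    list is bisected using a reduced replicate budget (one quarter) for
    interior probes; the frontier candidate is then confirmed with the
    full replicate set, advancing to the next candidate if confirmation
    fails.
    """
    cands = list(config.n_candidates)
    probe_reps = max(20, config.n_replicates // 4)
    estimates: dict[int, PowerEstimate] = {}

    def probe(i: int, reps: int) -> PowerEstimate:
        n = cands[i]
        est = estimate_power_at_n(dg_model, inf_model, goal, n, reps,
                                  seed=_replicate_seed(config.seed, 10_000 + n),
                                  sampler=config.sampler)
        estimates[n] = est
        return est

    lo, hi = 0, len(cands) - 1
    if probe(hi, probe_reps).power < config.power_target:
        frontier = None
    else:
        while lo < hi:
            mid = (lo + hi) // 2
            if probe(mid, probe_reps).power >= config.power_target:
                hi = mid
            else:
                lo = mid + 1
        frontier = lo

    recommended = None
    if frontier is not None:
        for i in range(frontier, len(cands)):
            est = probe(i, config.n_replicates)
            if est.power >= config.power_target:
                recommended = cands[i]
                break

    cats = [v for v in dg_model.categorical_levels
            if any(v in t.variables for t in dg_model.terms)]
    return PlanningResult(
        estimates=sorted(estimates.values(), key=lambda e: e.n),
        recommended_n=recommended, goal=goal, config=config,
        n_is_per_group=bool(cats))


# ---------------------------------------------------------------------
# conventional comparator
# ---------------------------------------------------------------------

@dataclass
class TTestParams:
    """Inputs to the classical two-sample power t-test sample size."""

    effect_size: float            # raw mean difference, units of the response
    pooled_sd: float
    alpha: float = 0.05
    power: float = 0.8
    sides: str = "two"

    def __post_init__(self) -> None:
        if self.effect_size == 0:
            raise ValueError("effect_size must be nonzero")
        if self.pooled_sd <= 0:
            raise ValueError("pooled_sd must be positive")
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValueError("alpha and power must lie in (0, 1)")
        if self.sides not in ("one", "two"):
            raise ValueError("sides must be 'one' or 'two'")


def _t_test_power(n_per_group: float, d: float, alpha: float, sides: str) -> float:
    df = 2.0 * n_per_group - 2.0
    ncp = abs(d) * sqrt(n_per_group / 2.0)
    if sides == "two":
        crit = stats.t.ppf(1 - alpha / 2, df)
        return float(stats.nct.sf(crit, df, ncp) + stats.nct.cdf(-crit, df, ncp))
    crit = stats.t.ppf(1 - alpha, df)
    return float(stats.nct.sf(crit, df, ncp))


def t_test_sample_size(params: TTestParams) -> int:
    """Total N (both groups) for a two-sample t-test at the requested power.

    Solves the noncentral-t power equation for the real-valued per-group
    size and returns ``ceil(2 * n_exact)``.
    """
    d = params.effect_size / params.pooled_sd
    if _t_test_power(2.0, d, params.alpha, params.sides) >= params.power:
        return 4
    f = lambda n: _t_test_power(n, d, params.alpha, params.sides) - params.power
    hi = 4.0
    while f(hi) < 0:
        hi *= 2
        if hi > 1e8:
            raise ValueError("no finite sample size reaches the requested power")
    n_exact = optimize.brentq(f, 2.0, hi, xtol=1e-10)
    return int(ceil(2.0 * n_exact - 1e-9))


# ---------------------------------------------------------------------
# scenario construction for overdispersed two-group counts
# ---------------------------------------------------------------------

def two_group_nb_scenario(baseline_mean: float, effect: float, pooled_sd: float,
                          response: str = "center_entries",
                          predictor: str = "strain",
                          levels: tuple[str, str] = ("A", "B"),
                          ) -> tuple[ModelSpec, float]:
    """Two-group negative-binomial ground truth matched to given moments.

    The groups have means ``baseline_mean`` and ``baseline_mean + effect``;
    the shared dispersion phi is chosen so that the average of the two
    group variances equals ``pooled_sd**2`` (Var = mu + mu^2/phi).  Returns
    the data-generation model and phi.
    """
    mu_a = float(baseline_mean)
    mu_b = mu_a + float(effect)
    excess = 2.0 * pooled_sd**2 - mu_a - mu_b
    if excess <= 0:
        raise ValueError("pooled variance must exceed the mean (overdispersion)")
    phi = (mu_a**2 + mu_b**2) / excess
    lo, hi = sorted(levels)
    dg = ModelSpec(
        response=response,
        terms=[LinearTerm("intercept"), LinearTerm("main_effect", (predictor,))],
        family=FamilySpec("negative_binomial"),
        priors=[
            PriorSpec("intercept", "point", {"value": float(np.log(mu_a))}),
            PriorSpec(f"{predictor}[{hi}]", "point",
                      {"value": float(np.log(mu_b / mu_a))}),
            PriorSpec("phi", "point", {"value": phi}),
        ],
        role="data_generation",
        categorical_levels={predictor: (lo, hi)},
    )
    return dg, phi
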