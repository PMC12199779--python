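"""Bayesian GLM specification: linear core, link, noise family, priors.

A :class:`ModelSpec` plays two roles.  As an *inference* model its free
parameters carry priors and are sampled given data.  As a *data-generation*
model every parameter is pinned to a point value, and the same structure
simulates data — the arrangement the planning module exploits: simulated
ground truth on one side, the model that will later analyse real data on
the other.

Categorical predictors are dummy (reference-level) coded with the reference
being the first level in lexicographic order.  Coefficient names follow the
``var[level]`` convention, interactions join components with ``:``.
"""

from __future__ import annotations

import itertools
import json
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import DataTable, VariableMeta
from .families import Family, get_family, get_link

__all__ = [
    "FamilySpec", "LinearTerm", "PriorSpec", "ModelSpec",
    "compatible_families", "default_priors", "validate_model",
    "linear_predictor", "build_design", "parse_formula",
]

PRIOR_DISTRIBUTIONS = ("normal", "student_t", "exponential", "half_normal",
                       "flat", "point")


@dataclass
class FamilySpec:
    """Noise family + link + auxiliary parameters (fixed values or None=free)."""

    family: str
    link: str | None = None
    aux_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        fam = get_family(self.family)
        if self.link is None:
            self.link = fam.default_link
        if self.link not in fam.links:
            raise ValueError(
                f"link {self.link!r} not compatible with family {self.family!r}"
                f" (allowed: {fam.links})")
        allowed = set(fam.aux_names)
        extra = set(self.aux_params) - allowed
        if extra:
            raise ValueError(f"family {self.family!r} takes no aux params {sorted(extra)}")
        for name in fam.aux:
            self.aux_params.setdefault(name, None)  # None = free parameter
        for name in fam.fixed_aux:
            if self.aux_params.get(name) is None:
                raise ValueError(f"family {self.family!r} requires fixed aux {name!r}")
        for name, val in self.aux_params.items():
            if val is not None and val <= 0:
                raise ValueError(f"aux parameter {name!r} must be positive, got {val}")

    @property
    def family_obj(self) -> Family:
        return get_family(self.family)

    def to_dict(self) -> dict:
        return {"family": self.family, "link": self.link,
                "aux_params": dict(self.aux_params)}

    @classmethod
    def from_dict(cls, d: dict) -> "FamilySpec":
        return cls(d["family"], d.get("link"), dict(d.get("aux_params", {})))


@dataclass(frozen=True)
class LinearTerm:
    """One term of the linear core: intercept, main effect or interaction."""

    kind: str
    variables: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("intercept", "main_effect", "interaction"):
            raise ValueError(f"unknown term kind {self.kind!r}")
        object.__setattr__(self, "variables", tuple(self.variables))
        if self.kind == "intercept" and self.variables:
            raise ValueError("intercept term takes no variables")
        if self.kind == "main_effect" and len(self.variables) != 1:
            raise ValueError("main effect needs exactly one variable")
        if self.kind == "interaction" and len(set(self.variables)) < 2:
            raise ValueError("interaction needs >=2 distinct variables")

    def to_dict(self) -> dict:
        return {"kind": self.kind, "variables": list(self.variables)}

    @classmethod
    def from_dict(cls, d: dict) -> "LinearTerm":
        return cls(d["kind"], tuple(d.get("variables", ())))


@dataclass
class PriorSpec:
    """Prior for one free parameter; ``point`` pins the parameter to a value."""

    parameter: str
    distribution: str
    hyperparams: dict = field(default_factory=dict)
    autoscaled: bool = False

    def __post_init__(self) -> None:
        if self.distribution not in PRIOR_DISTRIBUTIONS:
            raise ValueError(f"unknown prior distribution {self.distribution!r}")
        for key in ("scale", "rate"):
            if key in self.hyperparams and self.hyperparams[key] <= 0:
                raise ValueError(f"prior {key} must be strictly positive")

    def to_dict(self) -> dict:
        return {"parameter": self.parameter, "distribution": self.distribution,
                "hyperparams": dict(self.hyperparams), "autoscaled": self.autoscaled}

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        return cls(d["parameter"], d["distribution"], dict(d.get("hyperparams", {})),
                   d.get("autoscaled", False))

    # --- density / sampling on the constrained scale -----------------
    def logpdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        h = self.hyperparams
        if self.distribution == "normal":
            s = h["scale"]
            return -0.5 * ((x - h.get("loc", 0.0)) / s) ** 2 - np.log(s) - 0.5 * np.log(2 * np.pi)
        if self.distribution == "student_t":
            from scipy.stats import t as student_t
            return student_t.logpdf(x, df=h.get("df", 3), loc=h.get("loc", 0.0),
                                    scale=h["scale"])
        if self.distribution == "exponential":
            r = h["rate"]
            return np.where(x >= 0, np.log(r) - r * x, -np.inf)
        if self.distribution == "half_normal":
            s = h["scale"]
            return np.where(x >= 0,
                            0.5 * np.log(2 / np.pi) - np.log(s) - 0.5 * (x / s) ** 2,
                            -np.inf)
        if self.distribution == "flat":
            return np.zeros_like(x)
        raise ValueError("point priors have no density; parameter is fixed")

    def sample(self, rng: np.random.Generator, size=None) -> np.ndarray:
        h = self.hyperparams
        if self.distribution == "normal":
            return rng.normal(h.get("loc", 0.0), h["scale"], size)
        if self.distribution == "student_t":
            return h.get("loc", 0.0) + h["scale"] * rng.standard_t(h.get("df", 3), size)
        if self.distribution == "exponential":
            return rng.exponential(1.0 / h["rate"], size)
        if self.distribution == "half_normal":
            return np.abs(rng.normal(0.0, h["scale"], size))
        if self.distribution == "flat":
            return rng.normal(0.0, 10.0, size)  # initialization only
        return np.full(size if size is not None else (), h["value"], float)

    def median(self) -> float:
        h = self.hyperparams
        if self.distribution in ("normal", "student_t"):
            return float(h.get("loc", 0.0))
        if self.distribution == "exponential":
            return float(np.log(2.0) / h["rate"])
        if self.distribution == "half_normal":
            return float(0.6744897501960817 * h["scale"])
        if self.distribution == "flat":
            return 0.0
        return float(h["value"])


@dataclass
class ModelSpec:
    """Response + linear core + family/link + priors.

    ``categorical_levels`` fixes the level set (and hence the dummy coding)
    of each categorical predictor so that data-generation and inference
    models agree even when a simulated sample misses a level.
    """

    response: str
    terms: list[LinearTerm]
    family: FamilySpec
    priors: list[PriorSpec] = field(default_factory=list)
    role: str = "inference"
    categorical_levels: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in ("inference", "data_generation"):
            raise ValueError(f"unknown model role {self.role!r}")
        self.categorical_levels = {k: tuple(v) for k, v in self.categorical_levels.items()}
        if self.role == "data_generation":
            fixed = {p.parameter for p in self.priors if p.distribution == "point"}
            free = set(self.parameter_names()) - fixed
            if free:
                raise ValueError(
                    f"data-generation model needs point priors for all parameters; "
                    f"missing: {sorted(free)}")

    # --- parameter bookkeeping ---------------------------------------
    def coefficient_names(self) -> list[str]:
        names: list[str] = []
        for term in self.terms:
            names.extend(_term_column_names(term, self.categorical_levels))
        return names

    def aux_parameter_names(self) -> list[str]:
        fam = self.family.family_obj
        return [a for a in fam.aux if self.family.aux_params.get(a) is None
                or self.role == "data_generation"]

    def parameter_names(self) -> list[str]:
        return self.coefficient_names() + self.aux_parameter_names()

    def prior_for(self, parameter: str) -> PriorSpec | None:
        for p in self.priors:
            if p.parameter == parameter:
                return p
        return None

    def fixed_parameters(self) -> dict[str, float]:
        out = {p.parameter: float(p.hyperparams["value"])
               for p in self.priors if p.distribution == "point"}
        for name, val in self.family.aux_params.items():
            if val is not None:
                out[name] = float(val)
        return out

    def with_levels_from(self, data: DataTable) -> "ModelSpec":
        """Return a copy whose categorical level sets are taken from ``data``."""
        levels = dict(self.categorical_levels)
        for term in self.terms:
            for v in term.variables:
                if v in levels:
                    continue
                col = data.column(v)
                if not pd.api.types.is_numeric_dtype(col):
                    levels[v] = tuple(sorted(col.dropna().astype(str).unique()))
        return ModelSpec(self.response, list(self.terms), self.family,
                         list(self.priors), self.role, levels)

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "terms": [t.to_dict() for t in self.terms],
            "family": self.family.to_dict(),
            "priors": [p.to_dict() for p in self.priors],
            "role": self.role,
            "categorical_levels": {k: list(v) for k, v in self.categorical_levels.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            response=d["response"],
            terms=[LinearTerm.from_dict(t) for t in d["terms"]],
            family=FamilySpec.from_dict(d["family"]),
            priors=[PriorSpec.from_dict(p) for p in d.get("priors", [])],
            role=d.get("role", "inference"),
            categorical_levels={k: tuple(v) for k, v in
                                d.get("categorical_levels", {}).items()},
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


# ---------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------

def _levels_of(var: str, levels: Mapping[str, tuple[str, ...]]) -> tuple[str, ...] | None:
    return tuple(levels[var]) if var in levels else None


def _var_columns(var: str, levels: Mapping[str, tuple[str, ...]]) -> list[str]:
    lv = _levels_of(var, levels)
    if lv is None:
        return [var]
    # reference level = first in lexicographic order contributes 0
    ordered = sorted(lv)
    return [f"{var}[{l}]" for l in ordered[1:]]


def _term_column_names(term: LinearTerm, levels: Mapping[str, tuple[str, ...]]) -> list[str]:
    if term.kind == "intercept":
        return ["intercept"]
    parts = [_var_columns(v, levels) for v in term.variables]
    return [":".join(combo) for combo in itertools.product(*parts)]


def _encode_var(var: str, values: pd.Series, levels: Mapping[str, tuple[str, ...]]
                ) -> np.ndarray:
    lv = _levels_of(var, levels)
    if lv is None:
        return np.asarray(values, float)[:, None]
    ordered = sorted(lv)
    vals = values.astype(str).to_numpy()
    unknown = set(vals) - set(ordered)
    if unknown:
        raise ValueError(f"unknown level(s) {sorted(unknown)} for categorical {var!r}")
    return np.column_stack([(vals == l).astype(float) for l in ordered[1:]]) \
        if len(ordered) > 1 else np.zeros((len(vals), 0))


def build_design(model: ModelSpec, data: DataTable | pd.DataFrame
                 ) -> tuple[np.ndarray, list[str]]:
    """Build the design matrix (n_rows x n_coefficients) and column names."""
    df = data.df if isinstance(data, DataTable) else data
    blocks: list[np.ndarray] = []
    names: list[str] = []
    n = len(df)
    for term in model.terms:
        if term.kind == "intercept":
            blocks.append(np.ones((n, 1)))
            names.append("intercept")
            continue
        enc = [_encode_var(v, df[v], model.categorical_levels) for v in term.variables]
        cols = enc[0]
        for nxt in enc[1:]:
            cols = np.einsum("ni,nj->nij", cols, nxt).reshape(n, -1)
        blocks.append(cols)
        names.extend(_term_column_names(term, model.categorical_levels))
    X = np.hstack(blocks) if blocks else np.zeros((n, 0))
    return X, names


def linear_predictor(model: ModelSpec, parameters: Mapping[str, float],
                     row: Mapping[str, object]) -> float:
    """Evaluate eta for one predictor row; mean = inverse-link(eta)."""
    df = pd.DataFrame([dict(row)])
    X, names = build_design(model, df)
    missing = [n for n in names if n not in parameters]
    if missing:
        raise KeyError(f"parameters missing for coefficients: {missing}")
    beta = np.array([parameters[n] for n in names], float)
    return float(X[0] @ beta)


# ---------------------------------------------------------------------
# model-building helpers
# ---------------------------------------------------------------------

def compatible_families(meta: VariableMeta) -> list[FamilySpec]:
    """Families whose support matches a response variable's kind and bounds."""
    if meta.role != "response":
        raise ValueError("compatible_families expects a response variable")
    k = meta.kind
    if k == "count":
        out = [FamilySpec("poisson"), FamilySpec("negative_binomial")]
        ub = meta.upper_bound
        if ub is not None and ub > 0 and float(ub).is_integer():
            out.append(FamilySpec("binomial", aux_params={"trials": int(ub)}))
        return out
    if k == "proportion":
        return [FamilySpec("beta")]
    if k == "binary":
        return [FamilySpec("binomial", aux_params={"trials": 1})]
    if k == "continuous":
        if meta.lower_bound is not None and meta.lower_bound >= 0:
            return [FamilySpec("gamma"), FamilySpec("lognormal"),
                    FamilySpec("exponential"), FamilySpec("inverse_gaussian")]
        return [FamilySpec("normal")]
    raise ValueError(f"no supported noise family for kind {k!r}")


def _family_kind_findings(model: ModelSpec, meta: VariableMeta) -> list[str]:
    fam = model.family.family_obj
    if meta.kind not in fam.response_kinds:
        return [f"family {fam.name!r} incompatible with response kind {meta.kind!r}"]
    return []


def validate_model(model: ModelSpec, metas: Sequence[VariableMeta]) -> list[str]:
    """Check structural and compatibility invariants; findings, not exceptions."""
    findings: list[str] = []
    by_name = {m.name: m for m in metas}
    responses = [m for m in metas if m.role == "response"]
    if len(responses) != 1:
        findings.append(f"exactly one response required, found {len(responses)}")
    if model.response in by_name:
        rmeta = by_name[model.response]
        if rmeta.role != "response":
            findings.append(f"variable {model.response!r} is not marked as response")
        findings.extend(_family_kind_findings(model, rmeta))
    else:
        findings.append(f"response {model.response!r} has no variable metadata")
    for term in model.terms:
        for v in term.variables:
            m = by_name.get(v)
            if m is None:
                findings.append(f"term variable {v!r} has no variable metadata")
            elif m.role != "predictor":
                findings.append(f"term variable {v!r} does not have role=predictor")
    seen: set[str] = set()
    for p in model.priors:
        if p.parameter in seen:
            findings.append(f"duplicate prior for parameter {p.parameter!r}")
        seen.add(p.parameter)
    known = set(model.parameter_names())
    for p in model.priors:
        if p.parameter not in known:
            findings.append(f"prior for unknown parameter {p.parameter!r}")
    return findings


def default_priors(model: ModelSpec, data: DataTable) -> list[PriorSpec]:
    """Weakly informative priors autoscaled to the data.

    Identity link: intercept ~ normal(mean(y), 2.5*sd(y)), coefficients ~
    normal(0, 2.5*sd(y)/sd(x)), scale aux ~ exponential(1/sd(y)).  For
    non-identity links the response summaries move to the link scale:
    intercept centered at link(mean(y)) with scale 2.5, coefficients ~
    normal(0, 2.5/sd(x)), positive aux ~ exponential(1).  Deterministic
    given the data and invariant to row order.
    """
    df = data.df
    if model.response not in df.columns:
        raise KeyError(f"response {model.response!r} not in data")
    y = np.asarray(pd.to_numeric(df[model.response]), float)
    y = y[~np.isnan(y)]
    if y.size == 0:
        raise ValueError("no response values to autoscale priors")
    sd_y = float(np.std(y, ddof=1)) if y.size > 1 else 0.0
    identity = model.family.link == "identity"
    if identity and sd_y == 0:
        raise ValueError("zero-variance response: cannot autoscale priors")

    link = get_link(model.family.link)
    X, names = build_design(model, data)
    priors: list[PriorSpec] = []
    for j, name in enumerate(names):
        if name == "intercept":
            if identity:
                loc, scale = float(np.mean(y)), 2.5 * sd_y
            else:
                m = float(np.mean(y))
                if model.family.family == "binomial":
                    m = m / float(model.family.aux_params["trials"])
                eps = 1e-3
                m = min(max(m, eps), 1 - eps) if model.family.link in ("logit", "probit") else max(m, eps)
                loc, scale = float(link.forward(np.array(m))), 2.5
            priors.append(PriorSpec(name, "normal", {"loc": loc, "scale": scale},
                                    autoscaled=True))
        else:
            sd_x = float(np.std(X[:, j], ddof=1)) if X.shape[0] > 1 else 1.0
            sd_x = sd_x if sd_x > 0 else 1.0
            scale = (2.5 * sd_y / sd_x) if identity else 2.5 / sd_x
            priors.append(PriorSpec(name, "normal", {"loc": 0.0, "scale": scale},
                                    autoscaled=True))
    for aux in model.aux_parameter_names():
        rate = (1.0 / sd_y) if (identity and sd_y > 0) else 1.0
        priors.append(PriorSpec(aux, "exponential", {"rate": rate}, autoscaled=True))
    return priors


# ---------------------------------------------------------------------
# formula parsing (CLI convenience): "y ~ a + b + a:b"
# ---------------------------------------------------------------------

def parse_formula(formula: str, family: str, link: str | None = None,
                  aux_params: dict | None = None,
                  intercept: bool = True) -> ModelSpec:
    """Build a ModelSpec from a compact formula string."""
    m = re.match(r"^\s*([\w.]+)\s*~\s*(.*)$", formula)
    if not m:
        raise ValueError(f"cannot parse formula {formula!r}")
    response, rhs = m.group(1), m.group(2).strip()
    terms: list[LinearTerm] = [LinearTerm("intercept")] if intercept else []
    if rhs not in ("", "1"):
        for piece in (p.strip() for p in rhs.split("+")):
            if piece in ("", "1"):
                continue
            if piece == "0":
                terms = [t for t in terms if t.kind != "intercept"]
                continue
            if ":" in piece:
                terms.append(LinearTerm("interaction", tuple(piece.split(":"))))
            else:
                terms.append(LinearTerm("main_effect", (piece,)))
    return ModelSpec(response, terms, FamilySpec(family, link, dict(aux_params or {})))
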