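"""Reproducible analysis reports.

A report is an ordered list of elements (data summary, model spec, prior
table, diagnostics, interval table, effect matrix, PPC, LOO, planning
result, free text), each carrying its payload plus provenance (seed and a
cryptographic digest of data + model + sampler configuration).  The JSON
rendering is canonical and self-contained: it embeds everything needed to
re-execute the fit, and :func:`reproduce_fit` does exactly that, yielding
bitwise-identical draws.  The Markdown rendering is for humans.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .data_model import DataTable
from .inference import Diagnostics, PosteriorDraws, SamplerConfig, fit_model
from .model_spec import ModelSpec
from .planning import PlanningResult
from .summaries import summarize_parameters

__all__ = ["ReportElement", "Report", "default_report", "add_element",
           "render_report", "load_report", "reproduce_fit", "config_digest"]

ELEMENT_KINDS = ("data_summary", "model_spec", "prior_table", "diagnostics",
                 "interval_table", "effect_matrix", "ppc", "loo",
                 "planning_result", "free_text")

MANDATORY = ("data_summary", "model_spec", "prior_table", "diagnostics")


def now() -> str:
    """Wall-clock timestamp for callers who want stamped report elements."""
    return datetime.datetime.now(datetime.timezone.utc).isoformat(
        timespec="seconds")


def _canonical(obj) -> str:
    return json.dumps(obj, sort_keys=True, separators=(",", ":"))


def config_digest(*payloads) -> str:
    h = hashlib.sha256()
    for p in payloads:
        h.update(_canonical(p).encode())
    return h.hexdigest()


@dataclass
class ReportElement:
    kind: str
    payload: dict
    created_at: str = ""
    seed: int | None = None
    digest: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ELEMENT_KINDS:
            raise ValueError(f"unknown report element kind {self.kind!r}")
        # created_at stays empty unless the caller stamps it (see now()):
        # reports are then a pure function of the run, byte for byte
        # payload must round-trip losslessly through JSON
        if json.loads(_canonical(self.payload)) != self.payload:
            raise ValueError("payload does not round-trip through JSON")

    def to_dict(self) -> dict:
        return {"kind": self.kind, "payload": self.payload,
                "created_at": self.created_at, "seed": self.seed,
                "digest": self.digest}

    @classmethod
    def from_dict(cls, d: dict) -> "ReportElement":
        return cls(**d)


@dataclass
class Report:
    elements: list[ReportElement] = field(default_factory=list)
    tool_version: str = __version__

    @property
    def mandatory_complete(self) -> bool:
        kinds = {e.kind for e in self.elements}
        return (all(k in kinds for k in MANDATORY)
                and bool(kinds & {"interval_table", "planning_result"}))

    def to_dict(self) -> dict:
        return {"elements": [e.to_dict() for e in self.elements],
                "tool_version": self.tool_version,
                "mandatory_complete": self.mandatory_complete}


def _data_summary_payload(data: DataTable) -> dict:
    cols = {}
    for c in data.columns:
        col = data.column(c)
        entry: dict = {"n_missing": int(col.isna().sum())}
        try:
            vals = col.astype(float)
            entry.update(mean=float(np.nanmean(vals)), sd=float(np.nanstd(vals, ddof=1)))
        except (TypeError, ValueError):
            entry["n_levels"] = int(col.dropna().nunique())
        cols[c] = entry
    return {"n_rows": data.n_rows, "columns": cols,
            "provenance": data.provenance,
            "records": data.to_records()}


def default_report(result, data: DataTable | None = None,
                   diagnostics: Diagnostics | None = None,
                   mass: float = 0.95, method: str = "hdi") -> Report:
    """Assemble the mandatory elements for a completed fit or planning run.

    For a fit, pass the :class:`PosteriorDraws`, the fitted data and the
    diagnostics.  For planning, pass the :class:`PlanningResult` alone.
    """
    report = Report()
    if isinstance(result, PlanningResult):
        cfg = result.config.to_dict()
        dig = config_digest(result.goal.to_dict(), cfg)
        seed = result.config.seed
        add_element(report, ReportElement("data_summary", {
            "note": "planning run: data simulated from the data-generation model",
            "candidates": list(cfg["n_candidates"]),
        }, seed=seed, digest=dig))
        add_element(report, ReportElement("model_spec", {
            "goal": result.goal.to_dict()}, seed=seed, digest=dig))
        add_element(report, ReportElement("prior_table", {
            "note": "inference-model priors are autoscaled per replicate"},
            seed=seed, digest=dig))
        add_element(report, ReportElement("diagnostics", {
            "sampler": cfg["sampler"]}, seed=seed, digest=dig))
        add_element(report, ReportElement("planning_result", result.to_dict(),
                                          seed=seed, digest=dig))
        return report

    if not isinstance(result, PosteriorDraws) or data is None:
        raise ValueError("default_report needs (PosteriorDraws, data, "
                         "diagnostics) or a PlanningResult")
    draws = result
    if draws.config is None:
        raise ValueError("fit is incomplete: draws carry no sampler config")
    model_doc = draws.model.to_dict()
    cfg_doc = draws.config.to_dict()
    dig = config_digest(model_doc, cfg_doc, draws.data_digest)
    seed = draws.seed
    add_element(report, ReportElement("data_summary", _data_summary_payload(data),
                                      seed=seed, digest=dig))
    add_element(report, ReportElement("model_spec", {
        "model": model_doc, "sampler": cfg_doc, "data_digest": draws.data_digest},
        seed=seed, digest=dig))
    add_element(report, ReportElement("prior_table", {
        "priors": [p.to_dict() for p in draws.model.priors]},
        seed=seed, digest=dig))
    diag_payload = diagnostics.to_dict() if diagnostics is not None else \
        {"note": "diagnostics unavailable", "passed": False}
    add_element(report, ReportElement("diagnostics", diag_payload,
                                      seed=seed, digest=dig))
    add_element(report, ReportElement("interval_table", {
        "mass": mass, "method": method,
        "intervals": [s.to_dict() for s in
                      summarize_parameters(draws, mass, method)]},
        seed=seed, digest=dig))
    return report


def add_element(report: Report, element: ReportElement) -> Report:
    """Append an element; duplicates of a kind are allowed, order preserved."""
    report.elements.append(element)
    return report


def render_report(report: Report, format: str = "json") -> str:
    """Render to machine-readable JSON (canonical) or human-readable Markdown."""
    if not report.elements:
        raise ValueError("cannot render an empty report")
    if format == "json":
        return json.dumps(report.to_dict(), sort_keys=True, indent=1)
    if format == "markdown":
        lines = [f"# Analysis report (bayesize {report.tool_version})", ""]
        lines.append(f"Mandatory elements complete: {report.mandatory_complete}")
        for e in report.elements:
            lines += ["", f"## {e.kind}", "",
                      f"*created {e.created_at}, seed {e.seed}, "
                      f"config digest `{(e.digest or 'n/a')[:12]}`*", "",
                      "```json", json.dumps(e.payload, sort_keys=True, indent=1),
                      "```"]
        return "\n".join(lines)
    raise ValueError(f"unknown report format {format!r}")


def load_report(doc: str) -> Report:
    d = json.loads(doc)
    rep = Report(tool_version=d.get("tool_version", __version__))
    for ed in d["elements"]:
        ed = {k: v for k, v in ed.items() if k != "mandatory_complete"}
        rep.elements.append(ReportElement.from_dict(ed))
    return rep


def reproduce_fit(report: Report) -> tuple[PosteriorDraws, Diagnostics]:
    """Re-execute the fit a report describes, from its embedded provenance."""
    spec = next((e for e in report.elements if e.kind == "model_spec"), None)
    datasum = next((e for e in report.elements if e.kind == "data_summary"), None)
    if spec is None or datasum is None or "model" not in spec.payload:
        raise ValueError("report does not describe a reproducible fit")
    model = ModelSpec.from_dict(spec.payload["model"])
    config = SamplerConfig.from_dict(spec.payload["sampler"])
    data = DataTable.from_records(datasum.payload["records"],
                                  provenance=datasum.payload.get("provenance", ""))
    draws, diag = fit_model(model, data, config)
    if draws.data_digest != spec.payload.get("data_digest", draws.data_digest):
        raise ValueError("re-run data digest mismatch")
    return draws, diag
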