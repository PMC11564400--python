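"""End-to-end analysis pipeline on a twin cohort.

Runs the full modelling chain in the order a twin study would: load or
simulate the cohort, apply exclusions, residualize for age and sex,
standardize, estimate saturated twin correlations, univariate ACE
decompositions, then the requested causal model(s) with nested-model
comparison, simultaneous pruning of non-significant paths and — for the
extended cross-lagged model — trek decomposition of the two cross-lagged
covariances.  The same configuration and seed always produce an identical
report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import yaml

from . import __version__
from .analyze import (
    compare_models,
    decompose_cross_covariance,
    prune_nonsignificant,
    standardized_ace,
)
from .cohort import (
    ExclusionCriterion,
    TwinCohort,
    VariableSchema,
    apply_exclusions,
    mask_duplicate_instrument,
    read_cohort,
    residualize,
    standardize,
)
from .engine import fit
from .models import (
    build_ace_univariate,
    build_crosslag,
    build_doc,
    build_extended_crosslag,
    build_mrdoc,
    build_saturated_correlation_model,
)
from .simulate import SimConfig, simulate_structural

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("twinpath")


class PipelineError(RuntimeError):
    """An analysis stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run (usually loaded from YAML)."""

    #: either {"simulate": {...SimConfig fields...}} or {"path": "cohort.csv"}
    data: dict = field(default_factory=lambda: {"simulate": {}})
    schema: dict = field(default_factory=dict)
    exclusions: list[dict] = field(default_factory=list)
    residualize: dict = field(default_factory=dict)
    standardize: list[str] = field(default_factory=list)
    #: model family to run after the descriptive ladder:
    #: doc | mrdoc | crosslag | extended_crosslag (or empty for none)
    model: str = "extended_crosslag"
    traits: list[str] = field(default_factory=lambda: ["cd", "cs"])
    alpha: float = 0.05
    seed: int = 2024

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if int(self.seed) != self.seed:
            raise ValueError("seed must be an integer")

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        return cls(**dict(d))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return {
            "data": self.data,
            "schema": self.schema,
            "exclusions": self.exclusions,
            "residualize": self.residualize,
            "standardize": self.standardize,
            "model": self.model,
            "traits": self.traits,
            "alpha": self.alpha,
            "seed": self.seed,
        }

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            log.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


@_stage("load")
def _load(config: RunConfig) -> TwinCohort:
    if "simulate" in config.data:
        sim = dict(config.data["simulate"])
        sim.setdefault("seed", config.seed)
        return simulate_structural(SimConfig.from_dict(sim))
    schema = VariableSchema(**{
        k: tuple(v) if isinstance(v, list) else v for k, v in config.schema.items()
    })
    return read_cohort(config.data["path"], schema)


@_stage("preprocess")
def _preprocess(config: RunConfig, cohort: TwinCohort, report: dict) -> TwinCohort:
    if config.exclusions:
        criteria = [
            ExclusionCriterion(
                c["name"], tuple(c["columns"]), c.get("predicate", "missing")
            )
            for c in config.exclusions
        ]
        cohort, excl = apply_exclusions(cohort, criteria)
        report["exclusions"] = excl
    res = config.residualize
    targets = res.get("targets") or _default_targets(cohort)
    covariates = res.get("covariates", ["sex", "age_t1"])
    cohort = residualize(cohort, targets, covariates)
    cohort = standardize(cohort, config.standardize or targets)
    report["n_pairs"] = cohort.n_pairs
    report["zygosity"] = cohort.zygosity_counts()
    return cohort


def _default_targets(cohort: TwinCohort) -> list[str]:
    s = cohort.schema
    return [f"{tr}_t{ti}" for tr in s.traits for ti in s.times]


def _ci_overlap(lo1, hi1, lo2, hi2) -> bool:
    return max(lo1, lo2) <= min(hi1, hi2)


@_stage("descriptives")
def _descriptives(config: RunConfig, cohort: TwinCohort, report: dict) -> None:
    tokens = _default_targets(cohort)
    sat = fit(build_saturated_correlation_model(tokens), cohort, compute_se=False)
    report["saturated_correlations"] = sat.to_dict()
    report["univariate_ace"] = {}
    for tok in tokens:
        res = fit(build_ace_univariate(tok), cohort)
        comp = standardized_ace(res, tok)
        report["univariate_ace"][tok] = {
            "fit": res.to_dict(),
            "components": comp.to_dict(),
        }


@_stage("causal_models")
def _causal(config: RunConfig, cohort: TwinCohort, report: dict) -> None:
    if not config.model:
        return
    x, y = (f"{t}" for t in config.traits)
    warnings_out: list[str] = report.setdefault("warnings", [])
    models: dict[str, Any] = report.setdefault("models", {})

    if config.model == "doc":
        indicators = {t: [f"{t}_t1", f"{t}_t2"] for t in (x, y)}
        # the DoC design needs the traits' modes of inheritance to differ;
        # warn when their heritability intervals overlap
        ua = report.get("univariate_ace", {})
        keys = (f"{x}_t1", f"{y}_t1")
        if all(k in ua for k in keys):
            cis = []
            for k in keys:
                c = ua[k]["components"]
                se = c["se_h2"] or 0.0
                cis.append((c["h2"] - 1.96 * se, c["h2"] + 1.96 * se))
            if _ci_overlap(*cis[0], *cis[1]):
                warnings_out.append(
                    "DoC caveat: the traits' h2 confidence intervals overlap; "
                    "direction-of-causation tests require sufficiently "
                    "different ACE influences"
                )
        chol = fit(build_doc(x, y, "none", indicators=indicators), cohort)
        fits = {"none": chol}
        for direction in ("both", "xtoy", "ytox"):
            fits[direction] = fit(build_doc(x, y, direction, indicators=indicators), cohort)
        models["doc"] = {k: v.to_dict() for k, v in fits.items()}
        report["comparisons"] = [
            compare_models(fits["xtoy"], fits["both"]).to_dict(),
            compare_models(fits["ytox"], fits["both"]).to_dict(),
        ]
        return

    if config.model == "mrdoc":
        spec = build_mrdoc(f"{x}_t1", f"{y}_t1", cohort.schema.instrument or "pgs")
        res = fit(spec, mask_duplicate_instrument(cohort, cohort.schema.instrument or "pgs"))
        models["mrdoc"] = res.to_dict()
        p_inst = res.wald_p(spec.meta["instrument"]["strength"])
        if not np.isfinite(p_inst) or p_inst >= config.alpha:
            warnings_out.append(
                "weak instrument: the polygenic score does not significantly "
                "predict the exposure; causal interpretation skipped"
            )
            models["mrdoc"]["causal_interpretation"] = "skipped"
        return

    if config.model in ("crosslag", "extended_crosslag"):
        naive_spec = build_crosslag(x, y)
        naive = fit(naive_spec, cohort)
        models["crosslag"] = naive.to_dict()
        if config.model == "extended_crosslag":
            ext_spec = build_extended_crosslag(x, y)
            ext = fit(ext_spec, cohort)
            models["extended_crosslag"] = ext.to_dict()
            report["comparisons"] = [compare_models(naive, ext).to_dict()]
            pruned, row = prune_nonsignificant(ext_spec, ext, config.alpha, cohort)
            models["parsimonious"] = pruned.to_dict()
            report.setdefault("comparisons", []).append(row.to_dict())
            report["decomposition"] = {
                f"{x}_t1->{y}_t2": decompose_cross_covariance(
                    ext_spec, ext, f"{x}_t1_1", f"{y}_t2_1"
                ).to_dict(),
                f"{y}_t1->{x}_t2": decompose_cross_covariance(
                    ext_spec, ext, f"{y}_t1_1", f"{x}_t2_1"
                ).to_dict(),
            }
        else:
            pruned, row = prune_nonsignificant(naive_spec, naive, config.alpha, cohort)
            models["parsimonious"] = pruned.to_dict()
            report["comparisons"] = [row.to_dict()]
        return

    raise ValueError(f"unknown model family {config.model!r}")


def run_pipeline(config: RunConfig | Mapping) -> dict:
    """Execute the full analysis chain and return a JSON-serializable report."""
    if not isinstance(config, RunConfig):
        config = RunConfig.from_dict(config)
    report: dict[str, Any] = {
        "package": "twinpath",
        "version": __version__,
        "config_hash": config.hash(),
        "seed": config.seed,
        "stages": [],
    }
    cohort = _load(config)
    report["stages"].append("load")
    cohort = _preprocess(config, cohort, report)
    report["stages"].append("preprocess")
    _descriptives(config, cohort, report)
    report["stages"].append("descriptives")
    _causal(config, cohort, report)
    report["stages"].append("causal_models")
    return report
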