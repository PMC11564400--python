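"""Builders for the twin-model families.

Every builder returns a :class:`~twinpath.engine.ModelSpec` with the family's
scaling constraints and fixed structural constants baked in:

* additive-genetic (A) factors correlate 1.0 across MZ co-twins and 0.5
  across DZ co-twins (random mating assumed),
* shared-environment (C) factors correlate 1.0 within a pair in both groups,
* non-shared environment (E) factors are uncorrelated across co-twins.

Families
--------
``saturated correlations``
    Free within-person correlations constrained equal across birth order and
    zygosity; cross-twin correlations estimated separately per group.
``univariate ACE``
    A/C/E paths on one phenotype, optionally a latent factor with two
    indicators (first loading fixed to 1, equal indicator residuals).
``bivariate Cholesky``
    Triangular A/C/E loadings partitioning all (co)variances.
``direction of causation (DoC)``
    ACE per trait plus reciprocal or unidirectional causal paths between the
    phenotypes; cross-trait factor correlations fixed at zero so that the
    causal path carries the covariance.
``MRDoC``
    DoC with a polygenic-score instrument: instrument->exposure,
    instrument->outcome (pleiotropy) and exposure->outcome causal path, with
    residual cross-trait C and E covariances free and the A cross-trait
    covariance fixed at zero.
``cross-lagged`` / ``extended cross-lagged``
    Two-timepoint model with stability and cross-lagged paths, within-time
    A/C/E factor correlations at each age, and (extended) free cross-trait
    correlations between age-1 A/C factors and age-2 residual A/C factors;
    E cross-time correlations are fixed at zero for identification.
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

from .engine import DZ, GROUPS, MZ, ModelSpec

__all__ = [
    "FAMILIES",
    "build_saturated_correlation_model",
    "build_ace_univariate",
    "build_cholesky_bivariate",
    "build_doc",
    "build_mrdoc",
    "build_crosslag",
    "build_extended_crosslag",
    "build_model",
]

FAMILIES = (
    "saturated_corr",
    "ace_univariate",
    "cholesky_bivariate",
    "doc",
    "mrdoc",
    "crosslag",
    "extended_crosslag",
)


def _twin_cols(var: str) -> list[str]:
    return [f"{var}_1", f"{var}_2"]


def _set_genetic_cov(spec: ModelSpec, fac1: dict[int, str], fac2: dict[int, str],
                     value: str | float) -> None:
    """Covariance between two A-type factor families: within-twin as given,
    cross-twin scaled by 1.0 (MZ) / 0.5 (DZ)."""
    same = fac1 is fac2 or fac1 == fac2
    for t in (1, 2):
        spec.set_cov(fac1[t], fac2[t], value)
    pairs = [(fac1[1], fac2[2])] if same else [(fac1[1], fac2[2]), (fac1[2], fac2[1])]
    for a, b in pairs:
        spec.set_cov(a, b, value, groups=[MZ], scale=1.0)
        spec.set_cov(a, b, value, groups=[DZ], scale=0.5)


def _set_shared_cov(spec: ModelSpec, fac1: dict[int, str], fac2: dict[int, str],
                    value: str | float) -> None:
    """Covariance between two C-type factor families: identical within and
    across twins (shared environment is pair-level)."""
    same = fac1 is fac2 or fac1 == fac2
    for t in (1, 2):
        spec.set_cov(fac1[t], fac2[t], value)
    pairs = [(fac1[1], fac2[2])] if same else [(fac1[1], fac2[2]), (fac1[2], fac2[1])]
    for a, b in pairs:
        spec.set_cov(a, b, value)


def _set_unique_cov(spec: ModelSpec, fac1: dict[int, str], fac2: dict[int, str],
                    value: str | float) -> None:
    """Within-twin covariance between two E-type factor families (E is never
    shared across co-twins)."""
    for t in (1, 2):
        spec.set_cov(fac1[t], fac2[t], value)


def _add_ace_factors(spec: ModelSpec, tag: str) -> dict[str, dict[int, str]]:
    """Declare unit-variance A/C/E latent factors for phenotype ``tag`` on
    both twins, with the twin-design cross-twin structure."""
    fams = {}
    for comp in ("A", "C", "E"):
        fams[comp] = {t: f"{comp}_{tag}_{t}" for t in (1, 2)}
    _set_genetic_cov(spec, fams["A"], fams["A"], 1.0)
    _set_shared_cov(spec, fams["C"], fams["C"], 1.0)
    _set_unique_cov(spec, fams["E"], fams["E"], 1.0)
    return fams


def _declare_ace_variables(tag: str) -> list[str]:
    return [f"{comp}_{tag}_{t}" for comp in ("A", "C", "E") for t in (1, 2)]


# --------------------------------------------------------------------------
# saturated correlations
# --------------------------------------------------------------------------

def build_saturated_correlation_model(traits: Sequence[str]) -> ModelSpec:
    """Saturated correlation model on standardized per-twin variables.

    Within-person correlations share one parameter across birth order and
    zygosity; cross-twin within-trait and cross-twin cross-trait correlations
    are estimated separately for MZ and DZ pairs.  Variances are fixed at 1,
    so one trait yields 2 free parameters (rMZ, rDZ) and two traits yield 7.
    """
    traits = list(traits)
    if not traits:
        raise ValueError("need at least one trait")
    observed = [f"{t}_{i}" for i in (1, 2) for t in traits]
    spec = ModelSpec(observed, observed, name="saturated_corr")
    for v in observed:
        spec.set_cov(v, v, 1.0)
    for ta, tb in combinations(traits, 2):
        r = spec.add_parameter(f"r_{ta}_{tb}", 0.2, -0.99, 0.99, prunable=True)
        for i in (1, 2):
            spec.set_cov(f"{ta}_{i}", f"{tb}_{i}", r.name)
    for g in GROUPS:
        lab = g.lower()
        for t in traits:
            r = spec.add_parameter(f"r{lab}_{t}", 0.4, -0.99, 0.99, prunable=True)
            spec.set_cov(f"{t}_1", f"{t}_2", r.name, groups=[g])
        for ta, tb in combinations(traits, 2):
            r = spec.add_parameter(f"r{lab}_{ta}_{tb}", 0.1, -0.99, 0.99, prunable=True)
            spec.set_cov(f"{ta}_1", f"{tb}_2", r.name, groups=[g])
            spec.set_cov(f"{tb}_1", f"{ta}_2", r.name, groups=[g])
    return spec


# --------------------------------------------------------------------------
# measurement models
# --------------------------------------------------------------------------

def _add_measurement(
    spec: ModelSpec, factor_tag: str, indicators: Sequence[str]
) -> dict[int, str]:
    """Latent phenotype factor measured by per-twin indicator columns.

    The first loading is fixed to 1 to scale the factor.  With two
    indicators the second loading is free and the indicator residual
    variances are constrained equal; with a single indicator the residual
    variance is fixed at 0 (factor == observed score).
    """
    if not 1 <= len(indicators) <= 2:
        raise ValueError("a latent phenotype factor needs 1 or 2 indicators")
    factors = {t: f"F_{factor_tag}_{t}" for t in (1, 2)}
    for t in (1, 2):
        spec.set_path(factors[t], f"{indicators[0]}_{t}", 1.0)
    if len(indicators) == 2:
        lam = spec.add_parameter(f"lambda_{factor_tag}", 0.9)
        res = spec.add_parameter(f"res_{factor_tag}", 0.2, lower=0.0)
        for t in (1, 2):
            spec.set_path(factors[t], f"{indicators[1]}_{t}", lam.name)
            for ind in indicators:
                spec.set_cov(f"{ind}_{t}", f"{ind}_{t}", res.name)
    return factors


# --------------------------------------------------------------------------
# univariate ACE
# --------------------------------------------------------------------------

def build_ace_univariate(
    trait: str, indicators: Sequence[str] | None = None
) -> ModelSpec:
    """Univariate ACE decomposition of one phenotype.

    With ``indicators`` the decomposition applies to a latent factor with the
    measurement constraints above; otherwise to the observed score directly
    (columns ``{trait}_1`` / ``{trait}_2``).
    """
    if indicators is not None and len(indicators) < 2:
        raise ValueError("a latent ACE model requires two indicators")
    if indicators is None:
        observed = _twin_cols(trait)
        variables = observed + _declare_ace_variables(trait)
        spec = ModelSpec(variables, observed, name=f"ace_{trait}")
        phen = {t: f"{trait}_{t}" for t in (1, 2)}
    else:
        observed = [f"{ind}_{i}" for i in (1, 2) for ind in indicators]
        variables = (
            observed
            + [f"F_{trait}_{t}" for t in (1, 2)]
            + _declare_ace_variables(trait)
        )
        spec = ModelSpec(variables, observed, name=f"ace_{trait}")
        phen = _add_measurement(spec, trait, indicators)
    fams = _add_ace_factors(spec, trait)
    a = spec.add_parameter(f"a_{trait}", 0.55)
    c = spec.add_parameter(f"c_{trait}", 0.55)
    e = spec.add_parameter(f"e_{trait}", 0.35)
    for t in (1, 2):
        spec.set_path(fams["A"][t], phen[t], a.name)
        spec.set_path(fams["C"][t], phen[t], c.name)
        spec.set_path(fams["E"][t], phen[t], e.name)
    spec.meta = {"ace": {trait: (a.name, c.name, e.name)}}
    return spec


# --------------------------------------------------------------------------
# bivariate Cholesky
# --------------------------------------------------------------------------

def build_cholesky_bivariate(trait_x: str, trait_y: str) -> ModelSpec:
    """Triangular bivariate ACE decomposition (no causal paths).

    The first factor of each component loads on both traits; the second only
    on the second trait, partitioning all variances and covariances into
    A/C/E without any directed path between the phenotypes.
    """
    observed = [f"{t}_{i}" for i in (1, 2) for t in (trait_x, trait_y)]
    latents = [
        f"{comp}{k}_{t}" for comp in ("A", "C", "E") for k in (1, 2) for t in (1, 2)
    ]
    spec = ModelSpec(observed + latents, observed, name=f"cholesky_{trait_x}_{trait_y}")
    cross = {}
    for comp, setter in (
        ("A", _set_genetic_cov),
        ("C", _set_shared_cov),
        ("E", _set_unique_cov),
    ):
        for k in (1, 2):
            fam = {t: f"{comp}{k}_{t}" for t in (1, 2)}
            setter(spec, fam, fam, 1.0)
        lab = comp.lower()
        p11 = spec.add_parameter(f"{lab}11", 0.5)
        p21 = spec.add_parameter(f"{lab}21", 0.2)
        p22 = spec.add_parameter(f"{lab}22", 0.5)
        for t in (1, 2):
            spec.set_path(f"{comp}1_{t}", f"{trait_x}_{t}", p11.name)
            spec.set_path(f"{comp}1_{t}", f"{trait_y}_{t}", p21.name)
            spec.set_path(f"{comp}2_{t}", f"{trait_y}_{t}", p22.name)
        cross[comp] = (p11.name, p21.name, p22.name)
    spec.meta = {
        "ace": {
            trait_x: (cross["A"][0], cross["C"][0], cross["E"][0]),
        },
        "cholesky_cross": {
            (trait_x, trait_y): {
                comp: (cross[comp][0], cross[comp][1]) for comp in ("A", "C", "E")
            }
        },
    }
    return spec


# --------------------------------------------------------------------------
# direction of causation
# --------------------------------------------------------------------------

def build_doc(
    trait_x: str,
    trait_y: str,
    direction: str = "both",
    indicators: dict[str, Sequence[str]] | None = None,
) -> ModelSpec:
    """Direction-of-Causation model between two phenotypes.

    ACE components on each trait (cross-trait factor correlations fixed at
    zero) plus causal path(s): ``x -> y``, ``y -> x`` or both (reciprocal).
    ``direction='none'`` reduces to two independent ACE decompositions.  With
    ``indicators`` the causal paths act between latent phenotype factors.
    """
    if direction not in ("both", "xtoy", "ytox", "none"):
        raise ValueError(f"unknown direction {direction!r}")
    if indicators is None:
        observed = [f"{t}_{i}" for i in (1, 2) for t in (trait_x, trait_y)]
        variables = (
            observed + _declare_ace_variables(trait_x) + _declare_ace_variables(trait_y)
        )
        spec = ModelSpec(variables, observed, name=f"doc_{direction}")
        phen = {
            trait_x: {t: f"{trait_x}_{t}" for t in (1, 2)},
            trait_y: {t: f"{trait_y}_{t}" for t in (1, 2)},
        }
    else:
        observed = [
            f"{ind}_{i}"
            for i in (1, 2)
            for tr in (trait_x, trait_y)
            for ind in indicators[tr]
        ]
        variables = (
            observed
            + [f"F_{tr}_{t}" for tr in (trait_x, trait_y) for t in (1, 2)]
            + _declare_ace_variables(trait_x)
            + _declare_ace_variables(trait_y)
        )
        spec = ModelSpec(variables, observed, name=f"doc_{direction}")
        phen = {}
        for tr in (trait_x, trait_y):
            if len(indicators[tr]) == 2:
                phen[tr] = _add_measurement(spec, tr, indicators[tr])
            else:
                phen[tr] = _add_measurement(spec, tr, indicators[tr])
    spec.meta = {"ace": {}}
    for tr in (trait_x, trait_y):
        fams = _add_ace_factors(spec, tr)
        a = spec.add_parameter(f"a_{tr}", 0.55)
        c = spec.add_parameter(f"c_{tr}", 0.55)
        e = spec.add_parameter(f"e_{tr}", 0.35)
        for t in (1, 2):
            spec.set_path(fams["A"][t], phen[tr][t], a.name)
            spec.set_path(fams["C"][t], phen[tr][t], c.name)
            spec.set_path(fams["E"][t], phen[tr][t], e.name)
        spec.meta["ace"][tr] = (a.name, c.name, e.name)
    causal = {}
    if direction in ("both", "xtoy"):
        p = spec.add_parameter(f"causal_{trait_x}_to_{trait_y}", 0.1, prunable=True)
        for t in (1, 2):
            spec.set_path(phen[trait_x][t], phen[trait_y][t], p.name)
        causal["xtoy"] = p.name
    if direction in ("both", "ytox"):
        p = spec.add_parameter(f"causal_{trait_y}_to_{trait_x}", 0.1, prunable=True)
        for t in (1, 2):
            spec.set_path(phen[trait_y][t], phen[trait_x][t], p.name)
        causal["ytox"] = p.name
    spec.meta["causal"] = causal
    return spec


# --------------------------------------------------------------------------
# MRDoC
# --------------------------------------------------------------------------

def build_mrdoc(exposure: str, outcome: str, instrument: str = "pgs") -> ModelSpec:
    """MRDoC: unidirectional causation with a polygenic-score instrument.

    Paths: instrument -> exposure (instrument strength), instrument ->
    outcome (direct pleiotropy) and exposure -> outcome (causal).  The
    instrument correlates 1.0 / 0.5 across MZ / DZ co-twins.  With the
    pleiotropy path estimated, the residual cross-trait A and C covariances
    are free and the residual E covariance is fixed at 0 — the constraint
    that keeps the causal path identified alongside pleiotropy.  A corollary
    is that the causal path leans on the non-shared-environment contrast:
    when E influences on the exposure are (near) zero the model loses its
    leverage to determine causality, and when additionally the instrument
    path is zero the causal path is formally unidentified.
    """
    observed = [f"{v}_{i}" for i in (1, 2) for v in (exposure, outcome, instrument)]
    variables = (
        observed + _declare_ace_variables(exposure) + _declare_ace_variables(outcome)
    )
    spec = ModelSpec(variables, observed, name=f"mrdoc_{exposure}_{outcome}")
    phen = {tr: {t: f"{tr}_{t}" for t in (1, 2)} for tr in (exposure, outcome)}
    inst = {t: f"{instrument}_{t}" for t in (1, 2)}
    spec.meta = {"ace": {}}
    fams = {}
    for tr in (exposure, outcome):
        fams[tr] = _add_ace_factors(spec, tr)
        a = spec.add_parameter(f"a_{tr}", 0.55)
        c = spec.add_parameter(f"c_{tr}", 0.55)
        e = spec.add_parameter(f"e_{tr}", 0.35)
        for t in (1, 2):
            spec.set_path(fams[tr]["A"][t], phen[tr][t], a.name)
            spec.set_path(fams[tr]["C"][t], phen[tr][t], c.name)
            spec.set_path(fams[tr]["E"][t], phen[tr][t], e.name)
        spec.meta["ace"][tr] = (a.name, c.name, e.name)
    # the polygenic score behaves as an additive-genetic variable
    v = spec.add_parameter(f"v_{instrument}", 1.0, lower=1e-6)
    _set_genetic_cov(spec, inst, inst, v.name)
    p1 = spec.add_parameter("instrument_strength", 0.1, prunable=True)
    p2 = spec.add_parameter("pleiotropy", 0.1, prunable=True)
    d = spec.add_parameter(f"causal_{exposure}_to_{outcome}", 0.1, prunable=True)
    for t in (1, 2):
        spec.set_path(inst[t], phen[exposure][t], p1.name)
        spec.set_path(inst[t], phen[outcome][t], p2.name)
        spec.set_path(phen[exposure][t], phen[outcome][t], d.name)
    ra = spec.add_parameter("ra_residual", 0.1, -0.99, 0.99, prunable=True)
    rc = spec.add_parameter("rc_residual", 0.1, -0.99, 0.99, prunable=True)
    _set_genetic_cov(spec, fams[exposure]["A"], fams[outcome]["A"], ra.name)
    _set_shared_cov(spec, fams[exposure]["C"], fams[outcome]["C"], rc.name)
    spec.meta["causal"] = {"xtoy": d.name}
    spec.meta["instrument"] = {
        "strength": p1.name,
        "pleiotropy": p2.name,
        "variance": v.name,
    }
    return spec


# --------------------------------------------------------------------------
# cross-lagged models
# --------------------------------------------------------------------------

def build_crosslag(
    trait_x: str,
    trait_y: str,
    extended: bool = False,
    instrument: str | None = None,
    free_e_crosstime: bool = False,
) -> ModelSpec:
    """Two-timepoint cross-lagged twin model on observed scores.

    Age-1 phenotypes carry common A/C/E factors with free within-time
    cross-trait factor correlations; age-2 phenotypes receive stability
    paths, cross-lagged paths (x at age 1 -> y at age 2 and vice versa) and
    residual A/C/E factors with free within-time residual correlations.

    ``extended=True`` additionally frees the four cross-time cross-trait
    correlations between age-1 common factors and age-2 residual factors
    (two genetic, two shared-environmental); the corresponding non-shared
    (E) correlations stay fixed at zero to keep the model identified unless
    ``free_e_crosstime`` deliberately frees them.

    ``instrument`` optionally adds a per-twin polygenic score feeding the
    age-1 phenotypes, mirroring the synthetic cohort generator.
    """
    x, y = trait_x, trait_y
    observed = [
        f"{tr}_t{k}_{i}" for i in (1, 2) for k in (1, 2) for tr in (x, y)
    ]
    tags = [f"{x}1", f"{y}1", f"{x}r", f"{y}r"]
    latents = [f"{comp}_{tag}_{t}" for tag in tags for comp in ("A", "C", "E") for t in (1, 2)]
    if instrument is not None:
        observed = observed + _twin_cols(instrument)
    name = "extended_crosslag" if extended else "crosslag"
    spec = ModelSpec(observed + latents, observed, name=f"{name}_{x}_{y}")

    fams = {}
    for tag in tags:
        fams[tag] = _add_ace_factors(spec, tag)

    # factor loadings (paths from common/residual factors to phenotypes)
    loadings = {}
    for tag, var_t in ((f"{x}1", f"{x}_t1"), (f"{y}1", f"{y}_t1"),
                       (f"{x}r", f"{x}_t2"), (f"{y}r", f"{y}_t2")):
        trio = []
        for comp in ("A", "C", "E"):
            p = spec.add_parameter(f"{comp.lower()}_{tag}", 0.5 if comp != "E" else 0.3)
            for t in (1, 2):
                spec.set_path(f"{comp}_{tag}_{t}", f"{var_t}_{t}", p.name)
            trio.append(p.name)
        loadings[tag] = tuple(trio)

    # stability and cross-lagged regressions
    sx = spec.add_parameter(f"stab_{x}", 0.2, prunable=True)
    sy = spec.add_parameter(f"stab_{y}", 0.2, prunable=True)
    f_lag = spec.add_parameter(f"lag_{y}_to_{x}", 0.05, prunable=True)
    g_lag = spec.add_parameter(f"lag_{x}_to_{y}", 0.05, prunable=True)
    for t in (1, 2):
        spec.set_path(f"{x}_t1_{t}", f"{x}_t2_{t}", sx.name)
        spec.set_path(f"{y}_t1_{t}", f"{y}_t2_{t}", sy.name)
        spec.set_path(f"{y}_t1_{t}", f"{x}_t2_{t}", f_lag.name)
        spec.set_path(f"{x}_t1_{t}", f"{y}_t2_{t}", g_lag.name)

    # within-time cross-trait factor correlations
    within = {}
    for suffix, label in (("1", "t1"), ("r", "t2")):
        for comp, setter in (("A", _set_genetic_cov), ("C", _set_shared_cov),
                             ("E", _set_unique_cov)):
            r = spec.add_parameter(
                f"r{comp.lower()}_{label}", 0.2, -0.99, 0.99, prunable=True
            )
            setter(spec, fams[f"{x}{suffix}"][comp], fams[f"{y}{suffix}"][comp], r.name)
            within[(comp, label)] = r.name

    # cross-time confound correlations: age-1 common factors vs age-2
    # residual factors of the *other* trait
    crosstime = {}
    arc_tags = {}
    if extended:
        for comp, setter, label in (
            ("A", _set_genetic_cov, "ra"),
            ("C", _set_shared_cov, "rc"),
        ):
            for src, dst in ((f"{x}1", f"{y}r"), (f"{y}1", f"{x}r")):
                r = spec.add_parameter(
                    f"{label}_{src}_{dst}", 0.1, -0.99, 0.99, prunable=True
                )
                setter(spec, fams[src][comp], fams[dst][comp], r.name)
                crosstime[(comp, src, dst)] = r.name
                for t1 in (1, 2):
                    for t2 in (1, 2):
                        arc_tags[
                            frozenset((f"{comp}_{src}_{t1}", f"{comp}_{dst}_{t2}"))
                        ] = f"crosstime_{label}"
    if free_e_crosstime:
        for src, dst in ((f"{x}1", f"{y}r"), (f"{y}1", f"{x}r")):
            r = spec.add_parameter(f"re_{src}_{dst}", 0.05, -0.99, 0.99, prunable=True)
            _set_unique_cov(spec, fams[src]["E"], fams[dst]["E"], r.name)

    inst_meta = None
    if instrument is not None:
        inst = {t: f"{instrument}_{t}" for t in (1, 2)}
        v = spec.add_parameter(f"v_{instrument}", 1.0, lower=1e-6)
        _set_genetic_cov(spec, inst, inst, v.name)
        p1 = spec.add_parameter("instrument_strength", 0.05, prunable=True)
        p2 = spec.add_parameter("pleiotropy", 0.05, prunable=True)
        for t in (1, 2):
            spec.set_path(inst[t], f"{x}_t1_{t}", p1.name)
            spec.set_path(inst[t], f"{y}_t1_{t}", p2.name)
        inst_meta = {"strength": p1.name, "pleiotropy": p2.name, "variance": v.name}

    spec.meta = {
        "ace": {
            f"{x}_t1": loadings[f"{x}1"],
            f"{y}_t1": loadings[f"{y}1"],
        },
        "loadings": loadings,
        "lags": {"y_to_x": f_lag.name, "x_to_y": g_lag.name},
        "stability": {"x": sx.name, "y": sy.name},
        "within": within,
        "crosstime": crosstime,
        "arc_tags": arc_tags,
        "traits": (x, y),
    }
    if inst_meta:
        spec.meta["instrument"] = inst_meta
    return spec


def build_extended_crosslag(
    trait_x: str,
    trait_y: str,
    instrument: str | None = None,
    free_e_crosstime: bool = False,
) -> ModelSpec:
    """Cross-lagged model plus free cross-time A and C confound correlations."""
    return build_crosslag(
        trait_x,
        trait_y,
        extended=True,
        instrument=instrument,
        free_e_crosstime=free_e_crosstime,
    )


def build_model(family: str, **kwargs) -> ModelSpec:
    """Build a model by family name (configuration-file entry point)."""
    builders = {
        "saturated_corr": build_saturated_correlation_model,
        "ace_univariate": build_ace_univariate,
        "cholesky_bivariate": build_cholesky_bivariate,
        "doc": build_doc,
        "mrdoc": build_mrdoc,
        "crosslag": build_crosslag,
        "extended_crosslag": build_extended_crosslag,
    }
    if family not in builders:
        raise ValueError(f"unknown model family {family!r}; choose from {FAMILIES}")
    return builders[family](**kwargs)
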