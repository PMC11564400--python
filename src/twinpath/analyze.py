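"""Model comparison, path pruning, standardized ACE shares and trek
decomposition of model-implied covariances.

The decomposition enumerates Wright path-tracing routes (treks): a chain of
one-headed paths traced backward from the first variable, at most one
two-headed arc, then one-headed paths forward to the second variable.  Each
trek contributes the product of its path coefficients and the two-headed
(co)variance; the trek total over all routes equals the reticular-formula
covariance entry exactly, and grouping treks by which arc they pass through
splits a cross-lagged covariance into direct, cross-time genetic (rA),
cross-time shared-environment (rC) and within-time + stability shares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .engine import MZ, FitResult, ModelSpec, fit, implied_moments

__all__ = [
    "ComparisonRow",
    "VarianceComponents",
    "DecompositionTable",
    "falconer",
    "chi_square_difference",
    "compare_models",
    "prune_nonsignificant",
    "standardized_ace",
    "cross_trait_covariance_shares",
    "decompose_cross_covariance",
]


def falconer(r_mz: float, r_dz: float) -> tuple[float, float, float]:
    """Falconer's moment estimators (h2, c2, e2) from cross-twin correlations.

    ``h2 = 2 (rMZ - rDZ)``, ``c2 = 2 rDZ - rMZ``, ``e2 = 1 - rMZ``.  For
    standardized data these coincide with the maximum-likelihood solution
    whenever the three-moment fit is exact (all components non-negative).
    """
    return (2.0 * (r_mz - r_dz), 2.0 * r_dz - r_mz, 1.0 - r_mz)


# --------------------------------------------------------------------------
# nested model comparison
# --------------------------------------------------------------------------

@dataclass
class ComparisonRow:
    """Chi-square difference test between a restricted and a full model."""

    restricted: str
    full: str
    delta_chi2: float
    delta_df: int
    p_value: float
    delta_aic: float

    @property
    def preferred(self) -> str:
        return "restricted" if self.delta_aic <= 0 else "full"

    def to_dict(self) -> dict:
        return {
            "restricted": self.restricted,
            "full": self.full,
            "delta_chi2": float(self.delta_chi2),
            "delta_df": int(self.delta_df),
            "p_value": float(self.p_value),
            "delta_aic": float(self.delta_aic),
            "preferred": self.preferred,
        }


def chi_square_difference(delta_minus2ll: float, delta_df: int) -> float:
    """Tail probability of a chi-square difference test."""
    if delta_df <= 0:
        raise ValueError("delta_df must be positive")
    if delta_minus2ll < 0:
        raise ValueError("chi-square difference must be non-negative")
    return float(stats.chi2.sf(delta_minus2ll, delta_df))


def compare_models(restricted: FitResult, full: FitResult) -> ComparisonRow:
    """Likelihood-ratio and AIC comparison of two nested fits.

    The restricted model must have fewer free parameters and (names being
    available) a free-parameter set nested in the full model's.
    """
    ddf = full.n_free - restricted.n_free
    if ddf <= 0:
        raise ValueError(
            "restricted model must have fewer free parameters than the full model"
        )
    extra = set(restricted.spec.free_names()) - set(full.spec.free_names())
    if extra:
        raise ValueError(f"restricted model frees parameters absent from full: {extra}")
    delta = restricted.minus2ll - full.minus2ll
    if delta < -1e-6:
        raise ValueError(
            f"restricted -2lnL below full by {-delta:.3g}: "
            "the full model likely failed to converge"
        )
    delta = max(delta, 0.0)
    return ComparisonRow(
        restricted=restricted.spec.name,
        full=full.spec.name,
        delta_chi2=delta,
        delta_df=ddf,
        p_value=float(stats.chi2.sf(delta, ddf)),
        delta_aic=restricted.aic - full.aic,
    )


# --------------------------------------------------------------------------
# pruning
# --------------------------------------------------------------------------

def prune_nonsignificant(
    spec: ModelSpec,
    fitted: FitResult,
    alpha: float,
    data,
    **fit_kwargs,
) -> tuple[FitResult, ComparisonRow]:
    """Fix all non-significant free structural paths to zero and refit.

    All prunable parameters whose two-sided Wald p-value is >= ``alpha`` in
    the full model are restricted to zero simultaneously (not stepwise); the
    remaining parameters restart from the full-model estimates.  Returns the
    parsimonious fit and its chi-square comparison against the full model.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    pruned = spec.copy()
    dropped = []
    for name in spec.free_names():
        par = spec.parameters[name]
        pruned.parameters[name].start = fitted.estimates[name]
        if not par.prunable:
            continue
        p = fitted.wald_p(name)
        if np.isnan(p):
            warnings.warn(
                f"no standard error for {name!r}; kept despite pruning", RuntimeWarning
            )
            continue
        if p >= alpha:
            dropped.append(name)
            pruned.fix(name, 0.0)
    pruned.name = spec.name + "_parsimonious"
    if not dropped:
        row = ComparisonRow(spec.name, spec.name, 0.0, len(spec.free_names()), 1.0, 0.0)
        return fitted, row
    ident = None
    from .engine import check_identification

    ident = check_identification(pruned)
    if not ident.identified:
        raise ValueError(
            f"pruned model not identified after fixing {dropped}; "
            f"deficient combinations: {ident.deficient}"
        )
    refit = fit(pruned, data, **fit_kwargs)
    return refit, compare_models(refit, fitted)


# --------------------------------------------------------------------------
# standardized variance components
# --------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    """Standardized h2 / c2 / e2 shares with delta-method uncertainty."""

    variable: str
    h2: float
    c2: float
    e2: float
    se_h2: float = np.nan
    se_c2: float = np.nan
    se_e2: float = np.nan

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.h2, self.c2, self.e2)

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "h2": float(self.h2),
            "c2": float(self.c2),
            "e2": float(self.e2),
            "se_h2": None if np.isnan(self.se_h2) else float(self.se_h2),
            "se_c2": None if np.isnan(self.se_c2) else float(self.se_c2),
            "se_e2": None if np.isnan(self.se_e2) else float(self.se_e2),
        }


def standardized_ace(fitted: FitResult, variable: str) -> VarianceComponents:
    """Standardized variance shares of one phenotype from a fitted model.

    ``h2 = a^2 / (a^2 + c^2 + e^2)`` and analogously for c2 / e2, with
    standard errors by the delta method from the parameter covariance.
    """
    ace = fitted.spec.meta.get("ace", {})
    if variable not in ace:
        raise KeyError(
            f"fit of {fitted.spec.name!r} carries no ACE parameters for "
            f"{variable!r}; available: {sorted(ace)}"
        )
    names = list(ace[variable])
    theta = np.array([fitted.estimates[n] for n in names])
    total = float(np.sum(theta**2))
    if total <= 0:
        raise ValueError(f"total variance of {variable!r} is not positive")
    shares = theta**2 / total

    ses = [np.nan] * 3
    if fitted.param_cov is not None:
        free = fitted.spec.free_names()
        try:
            idx = [free.index(n) for n in names]
        except ValueError:
            idx = None
        if idx is not None:
            sub = fitted.param_cov[np.ix_(idx, idx)]
            for i in range(3):
                # d s_i / d theta_j = 2 theta_i delta_ij / T - 2 theta_i^2 theta_j / T^2
                grad = -2.0 * theta[i] ** 2 * theta / total**2
                grad[i] += 2.0 * theta[i] / total
                var = float(grad @ sub @ grad)
                ses[i] = np.sqrt(var) if var > 0 else np.nan
    return VarianceComponents(variable, *shares, *ses)


def cross_trait_covariance_shares(
    fitted: FitResult, trait_x: str, trait_y: str
) -> dict[str, float]:
    """A/C/E shares of the cross-trait covariance in a Cholesky fit.

    The covariance flows through the first factor of each component
    (coefficient product of its two loadings); shares are signed fractions
    of the total implied cross-trait covariance.
    """
    meta = fitted.spec.meta.get("cholesky_cross", {})
    key = (trait_x, trait_y)
    if key not in meta:
        raise KeyError(f"fit carries no Cholesky cross-paths for {key}")
    parts = {
        comp: fitted.estimates[p1] * fitted.estimates[p2]
        for comp, (p1, p2) in meta[key].items()
    }
    total = sum(parts.values())
    if total == 0:
        raise ValueError("implied cross-trait covariance is zero")
    return {comp: v / total for comp, v in parts.items()}


# --------------------------------------------------------------------------
# trek decomposition
# --------------------------------------------------------------------------

TREK_GROUPS = ("direct", "cross_time_rA", "cross_time_rC", "within_time_stability")


@dataclass
class DecompositionTable:
    """Grouped trek contributions to one model-implied covariance entry."""

    from_var: str
    to_var: str
    total: float
    contributions: dict[str, float]
    percentages: dict[str, float] | None
    n_treks: int = 0

    def to_dict(self) -> dict:
        return {
            "from": self.from_var,
            "to": self.to_var,
            "total": float(self.total),
            "contributions": {k: float(v) for k, v in self.contributions.items()},
            "percentages": (
                None
                if self.percentages is None
                else {k: float(v) for k, v in self.percentages.items()}
            ),
            "n_treks": int(self.n_treks),
        }


def _paths_into(P: np.ndarray, graph: nx.DiGraph, target: int, cache: dict):
    """All directed paths ending at ``target``: (source, coefficient product,
    frozenset of edges).  Includes the empty path (target, 1, {})."""
    if target in cache:
        return cache[target]
    out = [(target, 1.0, frozenset())]
    for src in graph.predecessors(target):
        w = P[target, src]
        for s, prod, edges in _paths_into(P, graph, src, cache):
            out.append((s, prod * w, edges | {(src, target)}))
    cache[target] = out
    return out


def decompose_cross_covariance(
    spec: ModelSpec,
    fitted: FitResult | dict | None,
    from_var: str,
    to_var: str,
    group: str = MZ,
) -> DecompositionTable:
    """Split a model-implied covariance into grouped trek contributions.

    Treks are grouped by membership: routes through the direct one-headed
    path ``from_var -> to_var``; routes whose two-headed arc is a cross-time
    genetic (rA) or shared-environment (rC) correlation (arc tags provided by
    the model builder); all remaining routes (within-time correlations and
    stability paths).  Group sums are validated against the reticular-formula
    covariance entry; the model must be acyclic.
    """
    if isinstance(fitted, FitResult):
        values = fitted.estimates
    else:
        values = spec.theta_dict(fitted)
    for v in (from_var, to_var):
        if v not in spec._index:
            raise KeyError(f"unknown variable {v!r}")
    P, S = spec.build_matrices(group, values)
    graph = nx.DiGraph(
        [(j, i) for i, j in zip(*np.nonzero(P))]
    )  # edge src -> dst
    graph.add_nodes_from(range(len(spec.variables)))
    if not nx.is_directed_acyclic_graph(graph):
        raise ValueError(
            "trek decomposition is defined only for recursive (acyclic) models"
        )
    arc_tags = {
        frozenset(k): v for k, v in spec.meta.get("arc_tags", {}).items()
    }
    idx = spec._index
    names = spec.variables
    i_from, i_to = idx[from_var], idx[to_var]
    direct_edge = (i_from, i_to)

    cache: dict = {}
    back = _paths_into(P, graph, i_from, cache)
    fwd = _paths_into(P, graph, i_to, cache)
    contributions = dict.fromkeys(TREK_GROUPS, 0.0)
    n_treks = 0
    for s, w1, e1 in back:
        srow = S[s]
        for t, w2, e2 in fwd:
            arc = srow[t]
            if arc == 0.0:
                continue
            value = w1 * arc * w2
            n_treks += 1
            tag = arc_tags.get(frozenset((names[s], names[t])))
            if direct_edge in e1 or direct_edge in e2:
                # by construction a direct-path trek cannot carry a
                # cross-time confound arc: the partition must be clean
                assert tag is None, (
                    "trek contains both the direct path and a cross-time arc"
                )
                contributions["direct"] += value
            elif tag == "crosstime_ra":
                contributions["cross_time_rA"] += value
            elif tag == "crosstime_rc":
                contributions["cross_time_rC"] += value
            else:
                contributions["within_time_stability"] += value

    total = sum(contributions.values())
    implied = implied_moments(spec, values)[group][1]
    obs_idx = {v: i for i, v in enumerate(spec.observed)}
    if from_var in obs_idx and to_var in obs_idx:
        ref = implied[obs_idx[from_var], obs_idx[to_var]]
        if not np.isclose(total, ref, rtol=1e-9, atol=1e-9):
            raise RuntimeError(
                f"trek total {total!r} does not match implied covariance {ref!r}"
            )
    percentages = None
    if total != 0.0:
        percentages = {k: 100.0 * v / total for k, v in contributions.items()}
    return DecompositionTable(
        from_var, to_var, total, contributions, percentages, n_treks
    )
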