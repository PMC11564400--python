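"""Structural-model specification and full-information ML engine for twin-pair data.

A :class:`ModelSpec` holds, for each zygosity group, a one-headed path matrix
``P`` (regressions among latent and observed variables), a two-headed matrix
``S`` (variances and covariances of exogenous terms) and an observed-variable
filter.  The model-implied covariance of the observed vector follows the
reticular formulation

    Sigma = F (I - P)^{-1} S (I - P)^{-T} F^T

with means fixed at zero (phenotypes are residualized and standardized
upstream).  The engine evaluates the full-information maximum likelihood
(FIML) of twin-pair rows with arbitrary missingness, optimizes it, computes
Wald standard errors from a numerical Hessian, and checks local
identification from the rank of the moment Jacobian.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import linalg, optimize

__all__ = [
    "Parameter",
    "ModelSpec",
    "FitResult",
    "IdentificationResult",
    "implied_moments",
    "fiml_minus2ll",
    "fit",
    "fit_covariances",
    "check_identification",
]

MZ = "MZ"
DZ = "DZ"
GROUPS = (MZ, DZ)

_LOG_2PI = math.log(2.0 * math.pi)
_PENALTY = 1.0e12


# --------------------------------------------------------------------------
# model specification
# --------------------------------------------------------------------------

@dataclass
class Parameter:
    """A named free (or fixed) coefficient of a structural model."""

    name: str
    start: float
    lower: float = -np.inf
    upper: float = np.inf
    free: bool = True
    #: structural paths eligible for significance pruning (causal paths,
    #: cross-lags, factor correlations) — measurement loadings are not.
    prunable: bool = False


@dataclass
class _Entry:
    matrix: str  # "P" or "S"
    row: int
    col: int
    param: str | None
    value: float
    scale: float


class ModelSpec:
    """Per-group path (one-headed) and covariance (two-headed) matrices.

    Parameters are shared across groups and twins by default: assigning the
    same parameter name to several cells imposes the equality constraint.
    Group-specific structural constants (the DZ additive-genetic cross-twin
    multiplier of 0.5) enter through the ``scale`` argument.
    """

    def __init__(
        self,
        variables: Sequence[str],
        observed: Sequence[str],
        groups: Sequence[str] = GROUPS,
        name: str = "model",
    ):
        if len(set(variables)) != len(variables):
            raise ValueError("duplicate variable names")
        missing = set(observed) - set(variables)
        if missing:
            raise ValueError(f"observed variables not declared: {sorted(missing)}")
        self.name = name
        self.variables = list(variables)
        self.observed = list(observed)
        self.groups = tuple(groups)
        self.parameters: dict[str, Parameter] = {}
        self._entries: dict[str, list[_Entry]] = {g: [] for g in self.groups}
        self._index = {v: i for i, v in enumerate(self.variables)}
        #: builder-attached metadata (ACE parameter names, arc tags, ...)
        self.meta: dict = {}

    # -- construction -----------------------------------------------------

    def add_parameter(
        self,
        name: str,
        start: float,
        lower: float = -np.inf,
        upper: float = np.inf,
        free: bool = True,
        prunable: bool = False,
    ) -> Parameter:
        if name in self.parameters:
            raise ValueError(f"parameter {name!r} already defined")
        p = Parameter(name, float(start), float(lower), float(upper), free, prunable)
        self.parameters[name] = p
        return p

    def _resolve(self, value: str | float) -> tuple[str | None, float]:
        if isinstance(value, str):
            if value not in self.parameters:
                raise KeyError(f"unknown parameter {value!r}")
            return value, 0.0
        return None, float(value)

    def set_path(
        self,
        src: str,
        dst: str,
        value: str | float,
        groups: Iterable[str] | None = None,
        scale: float = 1.0,
    ) -> None:
        """One-headed path ``src -> dst`` (cell ``P[dst, src]``)."""
        param, const = self._resolve(value)
        r, c = self._index[dst], self._index[src]
        for g in groups or self.groups:
            self._entries[g].append(_Entry("P", r, c, param, const, scale))

    def set_cov(
        self,
        a: str,
        b: str,
        value: str | float,
        groups: Iterable[str] | None = None,
        scale: float = 1.0,
    ) -> None:
        """Two-headed arc between ``a`` and ``b`` (symmetric cell of ``S``)."""
        param, const = self._resolve(value)
        i, j = self._index[a], self._index[b]
        for g in groups or self.groups:
            self._entries[g].append(_Entry("S", i, j, param, const, scale))
            if i != j:
                self._entries[g].append(_Entry("S", j, i, param, const, scale))

    # -- bookkeeping ------------------------------------------------------

    def free_names(self) -> list[str]:
        return [p.name for p in self.parameters.values() if p.free]

    @property
    def n_free(self) -> int:
        return len(self.free_names())

    def start_vector(self) -> np.ndarray:
        return np.array(
            [self.parameters[n].start for n in self.free_names()], dtype=float
        )

    def bounds(self) -> list[tuple[float, float]]:
        return [
            (self.parameters[n].lower, self.parameters[n].upper)
            for n in self.free_names()
        ]

    def fix(self, name: str, value: float | None = None) -> None:
        """Fix a parameter (at ``value`` if given, else at its start)."""
        p = self.parameters[name]
        p.free = False
        if value is not None:
            p.start = float(value)

    def copy(self) -> "ModelSpec":
        out = ModelSpec(self.variables, self.observed, self.groups, self.name)
        for p in self.parameters.values():
            out.parameters[p.name] = Parameter(
                p.name, p.start, p.lower, p.upper, p.free, p.prunable
            )
        for g in self.groups:
            out._entries[g] = list(self._entries[g])
        import copy as _copy

        out.meta = _copy.deepcopy(self.meta)
        return out

    def theta_dict(self, theta: np.ndarray | Mapping[str, float] | None) -> dict[str, float]:
        """Full parameter-value mapping (free values merged over starts)."""
        values = {n: p.start for n, p in self.parameters.items()}
        if theta is None:
            return values
        if isinstance(theta, Mapping):
            values.update({k: float(v) for k, v in theta.items()})
            return values
        theta = np.asarray(theta, dtype=float)
        free = self.free_names()
        if theta.shape != (len(free),):
            raise ValueError(
                f"expected {len(free)} free-parameter values, got {theta.shape}"
            )
        values.update(dict(zip(free, theta)))
        return values

    # -- matrix assembly --------------------------------------------------

    def build_matrices(
        self, group: str, theta: np.ndarray | Mapping[str, float] | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        values = self.theta_dict(theta)
        nv = len(self.variables)
        P = np.zeros((nv, nv))
        S = np.zeros((nv, nv))
        for e in self._entries[group]:
            v = (values[e.param] if e.param is not None else e.value) * e.scale
            (P if e.matrix == "P" else S)[e.row, e.col] = v
        return P, S


# --------------------------------------------------------------------------
# compiled evaluation (hot path for optimization)
# --------------------------------------------------------------------------

class _CompiledSpec:
    """Pre-indexed matrices for fast repeated evaluation at new parameters.

    Fixed values and non-free parameters are baked into base matrices; free
    parameters are scattered in by fancy indexing.
    """

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        free = spec.free_names()
        pos = {n: i for i, n in enumerate(free)}
        nv = len(spec.variables)
        self.obs_idx = np.array([spec._index[v] for v in spec.observed])
        self.base: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self.scatter: dict[str, dict[str, np.ndarray]] = {}
        for g in spec.groups:
            P0 = np.zeros((nv, nv))
            S0 = np.zeros((nv, nv))
            idx = {"P": ([], [], [], []), "S": ([], [], [], [])}
            for e in spec._entries[g]:
                mat = P0 if e.matrix == "P" else S0
                if e.param is not None and spec.parameters[e.param].free:
                    rows, cols, ks, scales = idx[e.matrix]
                    rows.append(e.row)
                    cols.append(e.col)
                    ks.append(pos[e.param])
                    scales.append(e.scale)
                    mat[e.row, e.col] = 0.0
                else:
                    v = e.value if e.param is None else spec.parameters[e.param].start
                    mat[e.row, e.col] = v * e.scale
            self.base[g] = (P0, S0)
            self.scatter[g] = {
                m: tuple(np.asarray(a) for a in arrs) for m, arrs in idx.items()
            }
        self._eye = np.eye(nv)

    def implied_cov(self, group: str, theta: np.ndarray) -> np.ndarray:
        P0, S0 = self.base[group]
        P, S = P0.copy(), S0.copy()
        for mat, key in ((P, "P"), (S, "S")):
            rows, cols, ks, scales = self.scatter[group][key]
            if len(rows):
                mat[rows, cols] = theta[ks] * scales
        ImP = self._eye - P
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", linalg.LinAlgWarning)
            inv = linalg.solve(ImP, self._eye)
        if not np.all(np.isfinite(inv)) or np.abs(inv).max() > 1e12:
            raise ValueError(f"singular (I - P) in group {group}")
        full = inv @ S @ inv.T
        cov = full[np.ix_(self.obs_idx, self.obs_idx)]
        return 0.5 * (cov + cov.T)


# --------------------------------------------------------------------------
# implied moments
# --------------------------------------------------------------------------

def _implied_cov(spec: ModelSpec, group: str, values: Mapping[str, float]) -> np.ndarray:
    P, S = spec.build_matrices(group, values)
    nv = len(spec.variables)
    ImP = np.eye(nv) - P
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", linalg.LinAlgWarning)
            inv = linalg.solve(ImP, np.eye(nv))
    except linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise ValueError(
            f"singular (I - P) in group {group}: reciprocal paths do not admit "
            "a reduced form at these parameter values"
        ) from exc
    # guard against a numerically singular reciprocal block that solve accepts
    if not np.all(np.isfinite(inv)) or np.abs(inv).max() > 1e12:
        raise ValueError(
            f"singular (I - P) in group {group}: reciprocal paths do not admit "
            "a reduced form at these parameter values"
        )
    full = inv @ S @ inv.T
    obs = [spec._index[v] for v in spec.observed]
    cov = full[np.ix_(obs, obs)]
    cov = 0.5 * (cov + cov.T)
    return cov


def implied_moments(
    spec: ModelSpec, params: np.ndarray | Mapping[str, float] | None = None
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-group (mean vector, covariance matrix) implied by the model.

    Means are identically zero; the covariance follows
    ``F (I-P)^{-1} S (I-P)^{-T} F^T``.
    """
    values = spec.theta_dict(params)
    out = {}
    p = len(spec.observed)
    for g in spec.groups:
        cov = _implied_cov(spec, g, values)
        out[g] = (np.zeros(p), cov)
    return out


# --------------------------------------------------------------------------
# FIML likelihood
# --------------------------------------------------------------------------

@dataclass
class _PatternBlock:
    cols: np.ndarray       # indices of observed (non-missing) variables
    n: int                 # number of rows sharing the pattern
    scatter: np.ndarray    # sum_i x_i x_i' over those rows (observed entries)


def _extract_groups(data, spec: ModelSpec, zygosity_col: str = "zygosity"):
    """Accept a TwinCohort or DataFrame and return {group: ndarray}."""
    df = getattr(data, "data", data)
    if zygosity_col not in df.columns:
        raise ValueError(f"data lacks a {zygosity_col!r} column")
    missing = [c for c in spec.observed if c not in df.columns]
    if missing:
        raise ValueError(f"data lacks model variables: {missing}")
    out = {}
    for g in spec.groups:
        sub = df.loc[df[zygosity_col] == g, spec.observed]
        out[g] = sub.to_numpy(dtype=float)
    return out


def _prepare_patterns(X: np.ndarray) -> list[_PatternBlock]:
    if X.size == 0:
        return []
    mask = ~np.isnan(X)
    blocks = []
    # group rows by missingness pattern; sufficient statistics per pattern
    keys = np.packbits(mask, axis=1) if mask.shape[1] <= 64 else mask.astype(np.uint8)
    _, inverse = np.unique(keys, axis=0, return_inverse=True)
    for code in np.unique(inverse):
        rows = np.where(inverse == code)[0]
        cols = np.where(mask[rows[0]])[0]
        if cols.size == 0:
            continue  # fully missing rows contribute nothing
        sub = X[np.ix_(rows, cols)]
        blocks.append(_PatternBlock(cols, len(rows), sub.T @ sub))
    return blocks


def _pattern_minus2ll(cov: np.ndarray, blocks: list[_PatternBlock]) -> float:
    total = 0.0
    for b in blocks:
        sub = cov[np.ix_(b.cols, b.cols)]
        try:
            chol = linalg.cholesky(sub, lower=True)
        except linalg.LinAlgError:
            raise ValueError(
                "implied covariance not positive definite on missingness "
                f"pattern {b.cols.tolist()}"
            )
        logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
        quad = float(np.trace(linalg.cho_solve((chol, True), b.scatter)))
        total += b.n * (len(b.cols) * _LOG_2PI + logdet) + quad
    return total


def fiml_minus2ll(
    spec: ModelSpec,
    params: np.ndarray | Mapping[str, float] | None,
    data,
) -> float:
    """−2 log likelihood of twin-pair rows under the model, row-wise FIML.

    Each row contributes the multivariate-normal −2·log density of its
    observed subvector under its zygosity group's implied moments; missing
    entries are marginalized by dropping the corresponding rows/columns of
    the implied covariance.  Rows with no observed entries contribute 0.
    """
    groups = _extract_groups(data, spec)
    values = spec.theta_dict(params)
    total = 0.0
    for g in spec.groups:
        blocks = _prepare_patterns(groups[g])
        if not blocks:
            continue
        cov = _implied_cov(spec, g, values)
        total += _pattern_minus2ll(cov, blocks)
    return total


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

@dataclass
class FitResult:
    """Estimates, uncertainty and fit indices of an optimized model."""

    spec: ModelSpec
    estimates: dict[str, float]
    std_errors: dict[str, float]
    minus2ll: float
    n_free: int
    converged: bool
    identified: bool
    implied: dict[str, np.ndarray]
    param_cov: np.ndarray | None = None
    boundary: list[str] = field(default_factory=list)
    message: str = ""
    n_rows: int = 0

    @property
    def aic(self) -> float:
        return self.minus2ll + 2.0 * self.n_free

    def wald_z(self, name: str) -> float:
        se = self.std_errors.get(name, np.nan)
        if not np.isfinite(se) or se <= 0:
            return np.nan
        return self.estimates[name] / se

    def wald_p(self, name: str) -> float:
        from scipy.stats import norm

        z = self.wald_z(name)
        if not np.isfinite(z):
            return np.nan
        return 2.0 * float(norm.sf(abs(z)))

    def to_dict(self) -> dict:
        return {
            "model": self.spec.name,
            "estimates": {k: float(v) for k, v in self.estimates.items()},
            "std_errors": {
                k: (float(v) if np.isfinite(v) else None)
                for k, v in self.std_errors.items()
            },
            "minus2ll": float(self.minus2ll),
            "n_free": int(self.n_free),
            "aic": float(self.aic),
            "converged": bool(self.converged),
            "identified": bool(self.identified),
            "boundary": list(self.boundary),
            "n_rows": int(self.n_rows),
        }


def _numeric_hessian(f: Callable[[np.ndarray], float], x: np.ndarray) -> np.ndarray:
    k = len(x)
    steps = 1e-5 * np.maximum(np.abs(x), 1.0)
    H = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        hi = steps[i]
        ei = np.zeros(k)
        ei[i] = hi
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / hi**2
        for j in range(i + 1, k):
            hj = steps[j]
            ej = np.zeros(k)
            ej[j] = hj
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * hi * hj)
    return H


def _wald_from_hessian(
    H: np.ndarray, free: list[str]
) -> tuple[dict[str, float], np.ndarray | None]:
    """Delta-method parameter covariance from the Hessian of −2lnL."""
    try:
        cov = 2.0 * linalg.inv(H)
    except linalg.LinAlgError:
        return {n: np.nan for n in free}, None
    diag = np.diag(cov)
    ses = {}
    for n, v in zip(free, diag):
        ses[n] = math.sqrt(v) if v > 0 else np.nan
    return ses, cov


def _optimize(
    objective: Callable[[np.ndarray], float],
    x0: np.ndarray,
    bounds: list[tuple[float, float]],
    n_restarts: int,
    restart_seed: int,
    gtol: float = 1e-6,
    ftol: float = 1e-10,
):
    """Quasi-Newton minimization with seeded random restarts on failure."""
    best = None
    rng = np.random.default_rng(restart_seed)
    start = np.array(x0, dtype=float)
    for attempt in range(n_restarts + 1):
        res = optimize.minimize(
            objective,
            start,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 5000, "maxfun": 200000, "ftol": ftol, "gtol": gtol},
        )
        if best is None or res.fun < best.fun - 1e-9 or (res.success and not best.success):
            best = res
        if best.success and best.fun < _PENALTY:
            break
        scale = 0.2 * (1 + attempt)
        start = np.asarray(x0) + rng.normal(0.0, scale, size=len(x0))
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        start = np.clip(start, np.where(np.isfinite(lo), lo + 1e-6, start),
                        np.where(np.isfinite(hi), hi - 1e-6, start))
    return best


def _finish_fit(
    spec: ModelSpec,
    objective: Callable[[np.ndarray], float],
    res,
    n_rows: int,
    compute_se: bool,
    check_ident: bool,
) -> FitResult:
    free = spec.free_names()
    xhat = np.asarray(res.x, dtype=float)
    estimates = spec.theta_dict(xhat)
    boundary = []
    for n, (lo, hi) in zip(free, spec.bounds()):
        v = estimates[n]
        if (np.isfinite(lo) and abs(v - lo) < 1e-6) or (
            np.isfinite(hi) and abs(v - hi) < 1e-6
        ):
            boundary.append(n)
    if compute_se and free:
        H = _numeric_hessian(objective, xhat)
        ses, pcov = _wald_from_hessian(H, free)
    else:
        ses, pcov = {n: np.nan for n in free}, None
    identified = True
    if check_ident:
        identified = check_identification(spec, xhat).identified
    implied = {g: m[1] for g, m in implied_moments(spec, xhat).items()}
    converged = bool(res.success) and res.fun < _PENALTY
    return FitResult(
        spec=spec,
        estimates=estimates,
        std_errors=ses,
        minus2ll=float(res.fun),
        n_free=len(free),
        converged=converged,
        identified=identified,
        implied=implied,
        param_cov=pcov,
        boundary=boundary,
        message=str(res.message),
        n_rows=n_rows,
    )


def fit(
    spec: ModelSpec,
    data,
    compute_se: bool = True,
    check_ident: bool = False,
    n_restarts: int = 10,
    restart_seed: int = 20240910,
) -> FitResult:
    """Minimize the FIML −2lnL of ``spec`` over its free parameters.

    Quasi-Newton (bounded L-BFGS) from the stored start values with up to
    ``n_restarts`` seeded random restarts on failure.  Standard errors are
    delta-method values from a central-difference Hessian at the optimum;
    parameters within 1e-6 of a bound are flagged as boundary solutions.
    """
    groups = _extract_groups(data, spec)
    prepared = {g: _prepare_patterns(groups[g]) for g in spec.groups}
    n_rows = sum(len(groups[g]) for g in spec.groups)
    free = spec.free_names()
    compiled = _CompiledSpec(spec)

    def objective(theta: np.ndarray) -> float:
        total = 0.0
        try:
            for g in spec.groups:
                if not prepared[g]:
                    continue
                cov = compiled.implied_cov(g, theta)
                total += _pattern_minus2ll(cov, prepared[g])
        except ValueError:
            return _PENALTY + float(np.sum(np.square(theta)))
        if not np.isfinite(total):
            return _PENALTY
        return total

    if not free:
        res = optimize.OptimizeResult(
            x=np.empty(0), fun=objective(np.empty(0)), success=True, message="no free parameters"
        )
        return _finish_fit(spec, objective, res, n_rows, False, False)

    res = _optimize(objective, spec.start_vector(), spec.bounds(), n_restarts, restart_seed)
    out = _finish_fit(spec, objective, res, n_rows, compute_se, check_ident)
    if not out.converged:
        warnings.warn(
            f"model {spec.name!r} did not converge: {out.message}", RuntimeWarning
        )
    return out


def fit_covariances(
    spec: ModelSpec,
    covariances: Mapping[str, np.ndarray],
    ns: Mapping[str, int],
    compute_se: bool = True,
    n_restarts: int = 10,
    restart_seed: int = 20240910,
) -> FitResult:
    """ML fit of ``spec`` to per-group sample covariance matrices.

    Minimizes the multivariate-normal deviance
    ``sum_g n_g (log|Sigma_g| + tr(S_g Sigma_g^{-1}) − log|S_g| − p)``,
    which is the −2 log-likelihood ratio against the saturated model.  Used
    for worked examples whose inputs are printed correlation matrices.
    """
    p = len(spec.observed)
    sample = {}
    for g in spec.groups:
        S = np.asarray(covariances[g], dtype=float)
        if S.shape != (p, p):
            raise ValueError(f"group {g}: covariance must be {p}x{p}")
        sample[g] = S
    consts = {
        g: float(np.linalg.slogdet(sample[g])[1]) for g in spec.groups
    }

    def objective(theta: np.ndarray) -> float:
        values = spec.theta_dict(theta)
        total = 0.0
        try:
            for g in spec.groups:
                cov = _implied_cov(spec, g, values)
                chol = linalg.cholesky(cov, lower=True)
                logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
                quad = float(np.trace(linalg.cho_solve((chol, True), sample[g])))
                total += ns[g] * (logdet + quad - consts[g] - p)
        except (ValueError, linalg.LinAlgError):
            return _PENALTY + float(np.sum(np.square(theta)))
        if not np.isfinite(total):
            return _PENALTY
        return total

    res = _optimize(objective, spec.start_vector(), spec.bounds(), n_restarts, restart_seed)
    n_rows = int(sum(ns[g] for g in spec.groups))
    out = _finish_fit(spec, objective, res, n_rows, compute_se, False)
    if not out.converged:
        warnings.warn(
            f"model {spec.name!r} did not converge: {out.message}", RuntimeWarning
        )
    return out


# --------------------------------------------------------------------------
# local identification
# --------------------------------------------------------------------------

@dataclass
class IdentificationResult:
    identified: bool
    rank: int
    n_free: int
    deficient: list[dict[str, float]]

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.identified


def _vech(mat: np.ndarray) -> np.ndarray:
    idx = np.triu_indices(mat.shape[0])
    return mat[idx]


def check_identification(
    spec: ModelSpec,
    params: np.ndarray | Mapping[str, float] | None = None,
    step: float = 1e-6,
    rank_tol: float = 1e-8,
) -> IdentificationResult:
    """Local identification from the rank of the moment Jacobian.

    Stacks the unique implied-covariance entries of both groups, forms the
    Jacobian with respect to the free parameters by central differences, and
    declares the model locally identified iff the column rank equals the
    number of free parameters.  When deficient, returns a null-space basis as
    parameter-combination dictionaries.
    """
    free = spec.free_names()
    values = spec.theta_dict(params)
    x0 = np.array([values[n] for n in free], dtype=float)
    if not free:
        return IdentificationResult(True, 0, 0, [])

    def moments(x: np.ndarray) -> np.ndarray:
        vals = dict(values)
        vals.update(dict(zip(free, x)))
        parts = [_vech(_implied_cov(spec, g, vals)) for g in spec.groups]
        return np.concatenate(parts)

    k = len(free)
    J = np.empty((len(moments(x0)), k))
    for i in range(k):
        e = np.zeros(k)
        e[i] = step
        J[:, i] = (moments(x0 + e) - moments(x0 - e)) / (2.0 * step)
    sv = linalg.svdvals(J) if min(J.shape) else np.empty(0)
    tol = rank_tol * (sv[0] if sv.size else 1.0)
    rank = int(np.sum(sv > tol))
    identified = rank == k
    deficient: list[dict[str, float]] = []
    if not identified:
        _, _, Vt = linalg.svd(J, full_matrices=True)
        for row in Vt[rank:]:
            combo = {
                n: float(w) for n, w in zip(free, row) if abs(w) > 1e-6
            }
            deficient.append(combo)
    return IdentificationResult(identified, rank, k, deficient)
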