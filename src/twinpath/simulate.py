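"""Synthetic twin-cohort generation.

Two complementary generators make every downstream modelling stage testable
without access to restricted cohort data:

``simulate_structural``
    Direct structural simulation: latent A/C/E factor draws with the
    twin-design cross-twin correlations (A: 1.0 MZ / 0.5 DZ; C: 1.0 both;
    E: 0), a two-timepoint recursion with stability and cross-lagged
    effects, cross-time confound correlations between age-1 common factors
    and age-2 residual factors, and a polygenic score acting as a partly
    shared genetic instrument.

``simulate_from_model``
    Multivariate-normal sampling from the per-group implied moments of any
    :class:`~twinpath.engine.ModelSpec` — the exact distribution a fitted
    model claims for the data.

For matched parameterizations the two agree in distribution;
:func:`config_to_modelspec` builds the extended cross-lagged model whose
implied covariance equals the structural generator's, which the test-suite
uses as a moment-matching oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .cohort import TwinCohort, VariableSchema
from .engine import DZ, MZ, ModelSpec, implied_moments
from .models import build_extended_crosslag

__all__ = [
    "TraitShares",
    "SimConfig",
    "simulate_structural",
    "simulate_from_model",
    "config_to_modelspec",
]


@dataclass(frozen=True)
class TraitShares:
    """Standardized variance shares of one trait at one time (sum to 1)."""

    a2: float
    c2: float
    e2: float

    def validate(self, label: str) -> None:
        for v in (self.a2, self.c2, self.e2):
            if v < 0:
                raise ValueError(f"{label}: negative variance share")
        if abs(self.a2 + self.c2 + self.e2 - 1.0) > 1e-10:
            raise ValueError(f"{label}: variance shares must sum to 1")

    def paths(self) -> tuple[float, float, float]:
        return (np.sqrt(self.a2), np.sqrt(self.c2), np.sqrt(self.e2))


def _default_shares() -> TraitShares:
    # illustrative of strongly familial early-childhood measures:
    # modest heritability, dominant shared environment, small E
    return TraitShares(0.3, 0.6, 0.1)


@dataclass
class SimConfig:
    """Generating parameters of the structural twin-cohort simulator.

    Defaults describe a cohort of preschool twin pairs with two traits
    (cognitive development ``cd`` and cognitive stimulation ``cs``) measured
    at two ages: strongly shared-environmental variance shares, moderate
    within-age factor correlations, modest stability, small bidirectional
    cross-lagged effects, cross-time genetic / shared-environment confound
    correlations, and a weak polygenic-score instrument.
    """

    trait_x: str = "cd"
    trait_y: str = "cs"
    shares_x_t1: TraitShares = field(default_factory=_default_shares)
    shares_y_t1: TraitShares = field(default_factory=_default_shares)
    shares_x_t2: TraitShares = field(default_factory=_default_shares)
    shares_y_t2: TraitShares = field(default_factory=_default_shares)
    # within-time cross-trait factor correlations (age 1 / age 2 residual)
    ra_t1: float = 0.35
    rc_t1: float = 0.50
    re_t1: float = 0.10
    ra_t2: float = 0.35
    rc_t2: float = 0.50
    re_t2: float = 0.10
    # autoregressive stability and cross-lagged effects
    stability_x: float = 0.25
    stability_y: float = 0.25
    lag_y_to_x: float = 0.10   # trait_y at age 1 -> trait_x at age 2
    lag_x_to_y: float = 0.11   # trait_x at age 1 -> trait_y at age 2
    # cross-time confounds: age-1 common factor <-> other trait's age-2
    # residual factor
    ra_cross: float = 0.20
    rc_cross: float = 0.35
    # polygenic-score instrument: strength (-> trait_x) and pleiotropy
    p1: float = 0.05
    p2: float = 0.05
    # covariate effects on the raw scores (removed by residualization)
    sex_effect: float = 0.10
    age_effect: float = 0.15
    n_mz: int = 2000
    n_dz: int = 3000
    missing_rate: float = 0.10
    seed: int = 2024

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        for label in ("shares_x_t1", "shares_y_t1", "shares_x_t2", "shares_y_t2"):
            getattr(self, label).validate(label)
        for label in ("ra_t1", "rc_t1", "re_t1", "ra_t2", "rc_t2", "re_t2",
                      "ra_cross", "rc_cross"):
            v = getattr(self, label)
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"{label} must lie in [-1, 1], got {v}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_mz < 0 or self.n_dz < 0:
            raise ValueError("group sizes must be non-negative")

    # -- factor correlation blocks ---------------------------------------

    def _factor_corr(self, r_t1: float, r_t2: float, r_cross: float) -> np.ndarray:
        """Correlation of the per-twin factor vector [x1, y1, xr, yr]."""
        R = np.eye(4)
        R[0, 1] = R[1, 0] = r_t1
        R[2, 3] = R[3, 2] = r_t2
        R[0, 3] = R[3, 0] = r_cross
        R[1, 2] = R[2, 1] = r_cross
        return R

    def factor_blocks(self) -> dict[str, np.ndarray]:
        return {
            "A": self._factor_corr(self.ra_t1, self.ra_t2, self.ra_cross),
            "C": self._factor_corr(self.rc_t1, self.rc_t2, self.rc_cross),
            "E": self._factor_corr(self.re_t1, self.re_t2, 0.0),
        }

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        for key in ("shares_x_t1", "shares_y_t1", "shares_x_t2", "shares_y_t2"):
            if key in d and isinstance(d[key], Mapping):
                d[key] = TraitShares(**d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------

def _psd_factor(cov: np.ndarray, label: str, tol: float = 1e-8) -> np.ndarray:
    """Square root of a PSD matrix via eigendecomposition.

    Tolerates the exactly singular matrices that arise from perfectly shared
    factors (MZ genetic sharing of 1.0); raises if genuinely indefinite.
    """
    w, V = np.linalg.eigh(0.5 * (cov + cov.T))
    if w.min() < -tol * max(1.0, w.max()):
        raise ValueError(
            f"implied {label} covariance is not positive semi-definite "
            f"(min eigenvalue {w.min():.3e}); adjust the correlation "
            "parameters"
        )
    return V * np.sqrt(np.clip(w, 0.0, None))


def _pair_block(R: np.ndarray, kappa: float) -> np.ndarray:
    """Pair-level covariance [[R, kappa R], [kappa R, R]]."""
    return np.block([[R, kappa * R], [kappa * R, R]])


# --------------------------------------------------------------------------
# structural simulation
# --------------------------------------------------------------------------

def simulate_structural(config: SimConfig) -> TwinCohort:
    """Generate a twin cohort by direct structural simulation.

    Draw order per zygosity group (one seeded generator stream, MZ first):
    A factors, C factors, E factors, polygenic score, sex, age at each wave,
    then the missingness mask.  Age-1 scores combine the instrument and the
    age-1 common factors; age-2 scores add stability and cross-lagged
    contributions of the age-1 scores to fresh residual factors that carry
    the configured cross-time correlations with the age-1 factors.
    """
    config.validate()
    blocks = config.factor_blocks()
    # fail before sampling if any implied latent covariance is indefinite
    factors = {}
    for kappa, grp in ((1.0, MZ), (0.5, DZ)):
        factors[(grp, "A")] = _psd_factor(
            _pair_block(blocks["A"], kappa), f"{grp} genetic-factor"
        )
    chol_c = _psd_factor(blocks["C"], "shared-environment factor")
    chol_e = _psd_factor(blocks["E"], "non-shared factor")

    rng = np.random.default_rng(config.seed)
    x, y = config.trait_x, config.trait_y
    ax1, cx1, ex1 = config.shares_x_t1.paths()
    ay1, cy1, ey1 = config.shares_y_t1.paths()
    ax2, cx2, ex2 = config.shares_x_t2.paths()
    ay2, cy2, ey2 = config.shares_y_t2.paths()

    frames = []
    for grp, n, kappa in ((MZ, config.n_mz, 1.0), (DZ, config.n_dz, 0.5)):
        if n == 0:
            continue
        A = rng.standard_normal((n, 8)) @ factors[(grp, "A")].T
        C = rng.standard_normal((n, 4)) @ chol_c.T  # pair-level, shared exactly
        E = np.stack(
            [rng.standard_normal((n, 4)) @ chol_e.T for _ in (1, 2)], axis=1
        )  # (n, twin, factor) — independent across twins
        pgs_pair = rng.standard_normal((n, 2)) @ _psd_factor(
            np.array([[1.0, kappa], [kappa, 1.0]]), "polygenic-score"
        ).T
        sex1 = rng.integers(0, 2, n).astype(float)
        sex2 = sex1.copy() if grp == MZ else rng.integers(0, 2, n).astype(float)
        age1 = rng.normal(3.05, 0.15, n)
        age2 = age1 + rng.normal(1.0, 0.05, n)

        cols: dict[str, np.ndarray] = {}
        for twin, sex in ((1, sex1), (2, sex2)):
            Ax1, Ay1, Axr, Ayr = (A[:, 4 * (twin - 1) + j] for j in range(4))
            Cx1, Cy1, Cxr, Cyr = (C[:, j] for j in range(4))
            Ex1, Ey1, Exr, Eyr = (E[:, twin - 1, j] for j in range(4))
            pgs = pgs_pair[:, twin - 1]
            covar1 = config.sex_effect * (sex - 0.5) + config.age_effect * (age1 - 3.5)
            covar2 = config.sex_effect * (sex - 0.5) + config.age_effect * (age2 - 3.5)
            x1 = config.p1 * pgs + ax1 * Ax1 + cx1 * Cx1 + ex1 * Ex1
            y1 = config.p2 * pgs + ay1 * Ay1 + cy1 * Cy1 + ey1 * Ey1
            x2 = (config.stability_x * x1 + config.lag_y_to_x * y1
                  + ax2 * Axr + cx2 * Cxr + ex2 * Exr)
            y2 = (config.stability_y * y1 + config.lag_x_to_y * x1
                  + ay2 * Ayr + cy2 * Cyr + ey2 * Eyr)
            cols[f"{x}_t1_{twin}"] = x1 + covar1
            cols[f"{y}_t1_{twin}"] = y1 + covar1
            cols[f"{x}_t2_{twin}"] = x2 + covar2
            cols[f"{y}_t2_{twin}"] = y2 + covar2
            cols[f"pgs_{twin}"] = pgs
            cols[f"sex_{twin}"] = sex

        df = pd.DataFrame(cols)
        phen_cols = [f"{tr}_t{k}_{tw}" for tr in (x, y) for k in (1, 2)
                     for tw in (1, 2)] + ["pgs_1", "pgs_2"]
        if config.missing_rate > 0:
            mask = rng.random((n, len(phen_cols))) < config.missing_rate
            for j, colname in enumerate(phen_cols):
                df.loc[mask[:, j], colname] = np.nan
        df.insert(0, "zygosity", grp)
        df.insert(0, "pair_id", [f"{grp.lower()}{i:05d}" for i in range(n)])
        df["age_t1"] = age1
        df["age_t2"] = age2
        frames.append(df)

    data = pd.concat(frames, ignore_index=True)
    schema = VariableSchema(traits=(x, y), times=(1, 2), instrument="pgs")
    return TwinCohort(data[schema.columns()], schema)


# --------------------------------------------------------------------------
# model-implied sampling
# --------------------------------------------------------------------------

def simulate_from_model(
    spec: ModelSpec,
    params: Mapping[str, float] | np.ndarray | None,
    n_mz: int,
    n_dz: int,
    seed: int,
) -> pd.DataFrame:
    """Sample twin-pair rows from a model's per-group implied moments.

    Returns a data frame with ``pair_id``, ``zygosity`` and one column per
    observed model variable; reproducible given the seed (MZ drawn first).
    """
    moments = implied_moments(spec, params)
    rng = np.random.default_rng(seed)
    frames = []
    for grp, n in ((MZ, n_mz), (DZ, n_dz)):
        if n == 0:
            continue
        mean, cov = moments[grp]
        L = _psd_factor(cov, f"{grp} implied")
        draws = mean + rng.standard_normal((n, len(mean))) @ L.T
        df = pd.DataFrame(draws, columns=spec.observed)
        df.insert(0, "zygosity", grp)
        df.insert(0, "pair_id", [f"{grp.lower()}{i:05d}" for i in range(n)])
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# generator -> model bridge
# --------------------------------------------------------------------------

def config_to_modelspec(config: SimConfig, instrument: bool = True) -> ModelSpec:
    """Extended cross-lagged ModelSpec whose implied covariance equals the
    structural generator's (covariate effects aside).

    Start values are set to the generating values, so
    ``implied_moments(config_to_modelspec(cfg))`` is the closed-form
    covariance of :func:`simulate_structural` output (before covariate
    effects and missingness).
    """
    config.validate()
    x, y = config.trait_x, config.trait_y
    spec = build_extended_crosslag(x, y, instrument="pgs" if instrument else None)
    values = {}
    for tag, shares in ((f"{x}1", config.shares_x_t1), (f"{y}1", config.shares_y_t1),
                        (f"{x}r", config.shares_x_t2), (f"{y}r", config.shares_y_t2)):
        a, c, e = shares.paths()
        values[f"a_{tag}"] = a
        values[f"c_{tag}"] = c
        values[f"e_{tag}"] = e
    values.update({
        f"stab_{x}": config.stability_x,
        f"stab_{y}": config.stability_y,
        f"lag_{y}_to_{x}": config.lag_y_to_x,
        f"lag_{x}_to_{y}": config.lag_x_to_y,
        "ra_t1": config.ra_t1, "rc_t1": config.rc_t1, "re_t1": config.re_t1,
        "ra_t2": config.ra_t2, "rc_t2": config.rc_t2, "re_t2": config.re_t2,
        f"ra_{x}1_{y}r": config.ra_cross, f"ra_{y}1_{x}r": config.ra_cross,
        f"rc_{x}1_{y}r": config.rc_cross, f"rc_{y}1_{x}r": config.rc_cross,
    })
    if instrument:
        values.update({
            "instrument_strength": config.p1,
            "pleiotropy": config.p2,
            "v_pgs": 1.0,
        })
    for name, v in values.items():
        spec.parameters[name].start = float(v)
    return spec
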