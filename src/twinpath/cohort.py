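"""Twin-pair data model, delimited-text IO and preprocessing.

The cohort is a wide table with one row per twin pair: a pair identifier,
zygosity (``MZ``/``DZ``), per-twin phenotype scores for each (trait, time)
combination, an optional per-twin polygenic score, and covariates (per-twin
sex, pair-level age at each assessment).  Missing values are empty fields in
the file and ``NaN`` in memory.

Preprocessing mirrors the usual twin-study pipeline: pair-wise exclusion
filtering, ordinary-least-squares residualization of the phenotypes for age
and sex (pooled over both twins' observations), and z-standardization over
the pooled twin-level observations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .engine import DZ, MZ

__all__ = [
    "VariableSchema",
    "TwinCohort",
    "ExclusionCriterion",
    "SchemaError",
    "ParseError",
    "read_cohort",
    "write_cohort",
    "apply_exclusions",
    "mask_duplicate_instrument",
    "residualize",
    "standardize",
]


class SchemaError(ValueError):
    """A required column is missing or the schema is internally inconsistent."""


class ParseError(ValueError):
    """A cell could not be parsed as the expected type."""


@dataclass(frozen=True)
class VariableSchema:
    """Column layout of a wide twin-pair table.

    Phenotype columns follow ``{trait}_t{time}_{twin}`` (e.g. ``cd_t1_1``),
    per-twin covariates ``{name}_{twin}`` (e.g. ``sex_1``), pair-level
    covariates a single column (e.g. ``age_t1``), and the instrument
    ``{instrument}_{twin}``.  ``rename`` maps arbitrary input headers onto
    this convention.
    """

    traits: tuple[str, ...] = ("cd", "cs")
    times: tuple[int, ...] = (1, 2)
    twin_covariates: tuple[str, ...] = ("sex",)
    pair_covariates: tuple[str, ...] = ("age_t1", "age_t2")
    instrument: str | None = "pgs"
    pair_id: str = "pair_id"
    zygosity: str = "zygosity"
    rename: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        cols = self.columns()
        if len(set(cols)) != len(cols):
            raise SchemaError("duplicate column labels in schema")

    def phenotype_col(self, trait: str, time: int, twin: int) -> str:
        return f"{trait}_t{time}_{twin}"

    def twin_cols(self, name: str) -> list[str]:
        return [f"{name}_1", f"{name}_2"]

    def phenotype_columns(self) -> list[str]:
        return [
            self.phenotype_col(tr, ti, tw)
            for tr in self.traits
            for ti in self.times
            for tw in (1, 2)
        ]

    def numeric_columns(self) -> list[str]:
        cols = self.phenotype_columns()
        if self.instrument:
            cols += self.twin_cols(self.instrument)
        for c in self.twin_covariates:
            cols += self.twin_cols(c)
        cols += list(self.pair_covariates)
        return cols

    def columns(self) -> list[str]:
        return [self.pair_id, self.zygosity] + self.numeric_columns()

    def variable_columns(self, name: str) -> list[str]:
        """Columns holding twin-level observations of a variable token.

        A phenotype token like ``cd_t1`` or the instrument maps to its two
        per-twin columns; a per-twin covariate to ``{name}_1``/``{name}_2``;
        a pair-level covariate to its single column (used for both twins).
        """
        if name in self.pair_covariates:
            return [name]
        for tr in self.traits:
            for ti in self.times:
                if name == f"{tr}_t{ti}":
                    return self.twin_cols(name)
        if name == self.instrument or name in self.twin_covariates:
            return self.twin_cols(name)
        raise SchemaError(f"unknown variable token {name!r}")


@dataclass
class TwinCohort:
    """Wide table of twin pairs plus the schema describing its columns."""

    data: pd.DataFrame
    schema: VariableSchema

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        df = self.data
        s = self.schema
        for col in (s.pair_id, s.zygosity):
            if col not in df.columns:
                raise SchemaError(f"missing required column {col!r}")
        bad = set(df[s.zygosity].dropna().unique()) - {MZ, DZ}
        if bad:
            raise ValueError(f"zygosity codes must be MZ/DZ, found {sorted(bad)}")
        if df[s.pair_id].duplicated().any():
            dup = df.loc[df[s.pair_id].duplicated(), s.pair_id].iloc[0]
            raise ValueError(f"duplicate pair identifier {dup!r}")
        for col in s.phenotype_columns():
            if col in df.columns and not pd.api.types.is_numeric_dtype(df[col]):
                raise ParseError(f"phenotype column {col!r} is not numeric")

    @property
    def n_pairs(self) -> int:
        return len(self.data)

    def zygosity_counts(self) -> dict[str, int]:
        counts = self.data[self.schema.zygosity].value_counts()
        return {g: int(counts.get(g, 0)) for g in (MZ, DZ)}

    def with_data(self, df: pd.DataFrame) -> "TwinCohort":
        return TwinCohort(df, self.schema)


# --------------------------------------------------------------------------
# IO
# --------------------------------------------------------------------------

def read_cohort(path, schema: VariableSchema) -> TwinCohort:
    """Read a comma-separated wide twin table, validating against the schema.

    Empty fields become missing values.  A missing required column raises
    :class:`SchemaError` naming it; a non-numeric phenotype cell raises
    :class:`ParseError` with its row and column.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.replace("", np.nan)
    if schema.rename:
        df = df.rename(columns=schema.rename)
    for col in schema.columns():
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    for col in schema.numeric_columns():
        raw = df[col]
        converted = pd.to_numeric(raw, errors="coerce")
        bad = converted.isna() & raw.notna()
        if bad.any():
            row = int(np.where(bad)[0][0])
            raise ParseError(
                f"non-numeric value {raw.iloc[row]!r} in column {col!r}, row {row}"
            )
        df[col] = converted
    # normalize any two-level sex encoding to {0, 1}
    for c in schema.twin_covariates:
        for col in schema.twin_cols(c):
            levels = sorted(pd.unique(df[col].dropna()))
            if len(levels) == 2 and set(levels) != {0.0, 1.0}:
                df[col] = df[col].map({levels[0]: 0.0, levels[1]: 1.0})
    return TwinCohort(df.reset_index(drop=True), schema)


def write_cohort(cohort: TwinCohort, path) -> None:
    """Write the cohort back to comma-separated text (missing = empty field)."""
    cohort.data.to_csv(path, index=False, na_rep="")


# --------------------------------------------------------------------------
# exclusions
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ExclusionCriterion:
    """A named pair-level exclusion rule.

    ``predicate`` is ``"missing"`` (any listed column missing), ``"flagged"``
    (any listed column non-zero/true), or a callable mapping a column Series
    to a boolean Series.  A pair is removed when the rule fires in any listed
    column — removal is pair-wise, so a flag on either twin drops both.
    """

    name: str
    columns: tuple[str, ...]
    predicate: str | Callable[[pd.Series], pd.Series] = "missing"

    def mask(self, df: pd.DataFrame) -> pd.Series:
        for col in self.columns:
            if col not in df.columns:
                raise SchemaError(
                    f"exclusion criterion {self.name!r} references unknown "
                    f"column {col!r}"
                )
        hit = pd.Series(False, index=df.index)
        for col in self.columns:
            if self.predicate == "missing":
                hit |= df[col].isna()
            elif self.predicate == "flagged":
                hit |= df[col].fillna(0).astype(float) != 0
            else:
                hit |= self.predicate(df[col]).fillna(False).astype(bool)
        return hit


def apply_exclusions(
    cohort: TwinCohort, criteria: Sequence[ExclusionCriterion]
) -> tuple[TwinCohort, dict[str, int]]:
    """Drop pairs matching any criterion; report removal counts per criterion.

    Counts are of pairs matching each criterion (a pair may match several);
    ``total_removed`` counts distinct pairs dropped.
    """
    df = cohort.data
    report: dict[str, int] = {}
    overall = pd.Series(False, index=df.index)
    for crit in criteria:
        m = crit.mask(df)
        report[crit.name] = int(m.sum())
        overall |= m
    report["total_removed"] = int(overall.sum())
    report["retained"] = int((~overall).sum())
    return cohort.with_data(df.loc[~overall].reset_index(drop=True)), report


# --------------------------------------------------------------------------
# residualization and standardization
# --------------------------------------------------------------------------

def _twin_level_frame(
    cohort: TwinCohort, target: str, covariates: Sequence[str]
) -> tuple[pd.DataFrame, list[tuple[int, str]]]:
    """Stack both twins' observations of ``target`` with matched covariates.

    Returns the long frame (one row per pair x twin) and the (row, column)
    bookkeeping needed to write residuals back into the wide table.
    """
    s = cohort.schema
    tcols = s.variable_columns(target)
    if len(tcols) != 2:
        raise SchemaError(f"target {target!r} is not a per-twin variable")
    frames = []
    for twin, tcol in zip((1, 2), tcols):
        cols = {"__y": cohort.data[tcol]}
        for cov in covariates:
            ccols = s.variable_columns(cov)
            col = ccols[0] if len(ccols) == 1 else ccols[twin - 1]
            cols[cov] = cohort.data[col]
        sub = pd.DataFrame(cols)
        sub["__twin"] = twin
        sub["__row"] = np.arange(len(cohort.data))
        frames.append(sub)
    long = pd.concat(frames, ignore_index=True)
    return long, tcols


def residualize(
    cohort: TwinCohort, targets: Sequence[str], covariates: Sequence[str]
) -> TwinCohort:
    """Replace each target by its OLS residual on the covariates + intercept.

    The regression pools both twins' non-missing observations.  Observations
    with a missing covariate keep the target missing (no imputation).  A
    zero-variance covariate is dropped with a warning.
    """
    df = cohort.data.copy()
    for target in targets:
        long, tcols = _twin_level_frame(cohort, target, covariates)
        usable = []
        for cov in covariates:
            vals = long[cov].dropna()
            if len(vals) and float(np.nanvar(vals)) > 0:
                usable.append(cov)
            else:
                warnings.warn(
                    f"covariate {cov!r} has zero variance; dropped from the "
                    f"residualization of {target!r}",
                    UserWarning,
                )
        complete = long[["__y"] + usable].notna().all(axis=1)
        fit_rows = long.loc[complete]
        X = sm.add_constant(fit_rows[usable].to_numpy(float), has_constant="add")
        beta = sm.OLS(fit_rows["__y"].to_numpy(float), X).fit().params
        # predict for every row with complete covariates
        resid = np.full(len(long), np.nan)
        cov_ok = long[usable].notna().all(axis=1) & long["__y"].notna()
        Xa = sm.add_constant(
            long.loc[cov_ok, usable].to_numpy(float), has_constant="add"
        )
        resid[cov_ok.to_numpy()] = long.loc[cov_ok, "__y"].to_numpy(float) - Xa @ beta
        for twin, tcol in zip((1, 2), tcols):
            rows = long["__twin"] == twin
            df[tcol] = np.where(
                np.isnan(resid[rows.to_numpy()]), np.nan, resid[rows.to_numpy()]
            )
    return cohort.with_data(df)


def mask_duplicate_instrument(data, instrument: str = "pgs"):
    """Blank the second twin's instrument column for MZ pairs.

    MZ co-twins carry identical polygenic scores, so a model that treats both
    twins' scores as observed has an exactly singular MZ implied covariance.
    Masking the duplicate column lets FIML evaluate the proper marginal
    likelihood.  Accepts a TwinCohort or a plain data frame; returns the same
    kind.
    """
    df = getattr(data, "data", data).copy()
    col = f"{instrument}_2"
    if col not in df.columns:
        raise SchemaError(f"instrument column {col!r} not found")
    zcol = data.schema.zygosity if isinstance(data, TwinCohort) else "zygosity"
    df.loc[df[zcol] == MZ, col] = np.nan
    return data.with_data(df) if isinstance(data, TwinCohort) else df


def standardize(cohort: TwinCohort, targets: Sequence[str]) -> TwinCohort:
    """Z-score each target over the pooled twin-level non-missing values."""
    df = cohort.data.copy()
    for target in targets:
        cols = cohort.schema.variable_columns(target)
        pooled = np.concatenate([df[c].to_numpy(float) for c in cols])
        pooled = pooled[~np.isnan(pooled)]
        if pooled.size < 2:
            raise ValueError(f"variable {target!r} has fewer than 2 observations")
        sd = float(np.std(pooled, ddof=1))
        if sd == 0:
            raise ValueError(f"variable {target!r} has zero variance")
        mean = float(np.mean(pooled))
        for c in cols:
            df[c] = (df[c] - mean) / sd
    return cohort.with_data(df)
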