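"""Nuisance-variable removal and column standardization for regional volumes.

Each region's volume is replaced by its least-squares residual on a
confound design built from the cohort table: body mass index, head size,
two head-motion summaries, head position (x, y, z), scanner-table position,
acquisition site (one-hot), plus the derived terms age, age^2, sex,
sex*age and sex*age^2.  Residualization is per-column ordinary least
squares with an intercept, so residuals are exactly orthogonal to every
confound regressor and the operation is idempotent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["ConfoundSpec", "build_confound_design", "residualize_confounds", "standardize_columns"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfoundSpec:
    """Names of the cohort columns entering the confound design.

    ``continuous`` columns enter as-is; ``site`` expands to one-hot dummies
    with the first level dropped (the design carries a global intercept);
    age/sex terms (age, age^2, sex, sex*age, sex*age^2) are derived from
    ``age_col`` and ``sex_col``.
    """

    continuous: tuple[str, ...] = (
        "bmi",
        "head_size",
        "motion_task",
        "motion_rest",
        "pos_x",
        "pos_y",
        "pos_z",
        "table_pos",
    )
    site_col: str | None = "site"
    age_col: str = "age"
    sex_col: str = "sex"
    extra: tuple[str, ...] = field(default=())


def _sex_indicator(sex: pd.Series) -> np.ndarray:
    if sex.dtype == object or isinstance(sex.dtype, pd.CategoricalDtype):
        return (sex == "female").to_numpy(dtype=float)
    return sex.to_numpy(dtype=float)


def build_confound_design(cohort: pd.DataFrame, spec: ConfoundSpec) -> pd.DataFrame:
    """Assemble the confound design matrix (with intercept) from the cohort."""
    missing = [c for c in spec.continuous + spec.extra if c not in cohort.columns]
    if spec.site_col is not None and spec.site_col not in cohort.columns:
        missing.append(spec.site_col)
    for c in (spec.age_col, spec.sex_col):
        if c not in cohort.columns:
            missing.append(c)
    if missing:
        raise KeyError(f"cohort table lacks confound columns: {missing}")

    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(cohort))}
    for c in spec.continuous + spec.extra:
        cols[c] = cohort[c].to_numpy(dtype=float)
    age = cohort[spec.age_col].to_numpy(dtype=float)
    sex = _sex_indicator(cohort[spec.sex_col])
    cols["age"] = age
    cols["age_sq"] = age**2
    cols["sex"] = sex
    cols["sex_x_age"] = sex * age
    cols["sex_x_age_sq"] = sex * age**2
    design = pd.DataFrame(cols, index=cohort.index)
    if spec.site_col is not None:
        dummies = pd.get_dummies(
            cohort[spec.site_col], prefix=spec.site_col, drop_first=True, dtype=float
        )
        design = pd.concat([design, dummies], axis=1)
    return design


def residualize_confounds(
    volumes: pd.DataFrame,
    cohort: pd.DataFrame,
    spec: ConfoundSpec | None = None,
) -> pd.DataFrame:
    """Regress every region column on the confound design and keep residuals.

    Rows with any missing value (volumes or confounds) are dropped listwise
    with a logged count.  A rank-deficient design is fit by the minimum-norm
    least-squares solution with a warning; residuals are unaffected by which
    solution is chosen.
    """
    if len(volumes) != len(cohort):
        raise ValueError("volumes and cohort must have the same number of rows")
    spec = spec or ConfoundSpec()
    design = build_confound_design(cohort, spec)

    keep = ~(volumes.isna().any(axis=1).to_numpy() | design.isna().any(axis=1).to_numpy())
    if not keep.all():
        logger.info("listwise deletion dropped %d rows with missing values", (~keep).sum())
        volumes = volumes.loc[keep]
        design = design.loc[keep]

    zero_var = volumes.columns[volumes.std(axis=0, ddof=0) == 0]
    if len(zero_var):
        raise ValueError(f"regions with zero variance: {list(zero_var)}")

    C = design.to_numpy(dtype=float)
    V = volumes.to_numpy(dtype=float)
    if np.linalg.matrix_rank(C) < C.shape[1]:
        warnings.warn(
            "confound design is rank deficient; using minimum-norm least squares",
            stacklevel=2,
        )
    beta, *_ = np.linalg.lstsq(C, V, rcond=None)
    resid = V - C @ beta
    return pd.DataFrame(resid, index=volumes.index, columns=volumes.columns)


def standardize_columns(matrix: pd.DataFrame) -> pd.DataFrame:
    """Z-score each column to zero mean and unit variance.

    Uses the population (n-denominator) standard deviation; a zero-variance
    column is an error because it carries no co-variation signal.
    """
    X = matrix.to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    bad = matrix.columns[sd == 0]
    if len(bad):
        raise ValueError(f"zero-variance columns cannot be standardized: {list(bad)}")
    return pd.DataFrame((X - mu) / sd, index=matrix.index, columns=matrix.columns)
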