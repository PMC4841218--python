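"""Covariate adjustment by residualization.

The rhythm models never include covariates directly: demographic structure
and secular drift are removed first by regressing the outcome on dummy codes
for each level of each categorical covariate plus linear and quadratic
study-day terms, and the residuals are what the cosinor sees.  Continuous
outcomes use ordinary least squares; binary outcomes use a maximum-likelihood
logit, with response residuals (observed 0/1 minus fitted probability) so the
downstream variance-explained computation stays on one scale logic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)


@dataclass
class AdjustmentSpec:
    """What to regress out before rhythm fitting.

    ``categorical_covariates`` are expanded to one indicator per level with
    one reference level omitted; ``detrend`` adds linear and quadratic
    study-day terms (days since the earliest record, centered and scaled to
    [-1, 1] before squaring, for conditioning).
    """

    categorical_covariates: list[str] = field(default_factory=list)
    detrend: bool = True
    outcome_kind: str = "continuous"  # or "binary"

    def __post_init__(self):
        if self.outcome_kind not in ("continuous", "binary"):
            raise ValueError(f"unknown outcome_kind {self.outcome_kind!r}")


@dataclass
class ResidualSeries:
    """Adjusted outcome values paired with their clock times."""

    residual: np.ndarray
    time: np.ndarray  # local clock hours in [0, 24)
    n: int
    total_ss: float  # sum of squared deviations of residual from its mean
    index: pd.Index | None = None  # rows of the source frame that survived


def study_day_terms(dates) -> tuple[np.ndarray, np.ndarray]:
    """Centered/scaled linear and quadratic study-day regressors."""
    days = (
        pd.DatetimeIndex(dates).normalize()
        - pd.DatetimeIndex(dates).normalize().min()
    ).days.to_numpy(dtype=float)
    span = days.max()
    if span > 0:
        scaled = 2.0 * days / span - 1.0
    else:
        scaled = np.zeros_like(days)
    return scaled, scaled**2


def build_design(
    df: pd.DataFrame,
    spec: AdjustmentSpec,
    date_col: str = "local_date",
    reference_levels: dict | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Adjustment design matrix: intercept, dummies, optional detrend terms.

    ``reference_levels`` optionally fixes which level of each covariate is
    omitted (default: first observed level in sorted order); residuals are
    invariant to this choice.
    """
    cols = [np.ones(len(df))]
    names = ["intercept"]
    reference_levels = reference_levels or {}
    for cov in spec.categorical_covariates:
        if cov not in df.columns:
            raise KeyError(f"adjustment covariate {cov!r} not in data")
        levels = sorted(pd.unique(df[cov].dropna()))
        if len(levels) < 2:
            raise ValueError(f"covariate {cov!r} has fewer than 2 levels")
        ref = reference_levels.get(cov, levels[0])
        for lev in levels:
            if lev == ref:
                continue
            cols.append((df[cov] == lev).to_numpy(dtype=float))
            names.append(f"{cov}[{lev}]")
    if spec.detrend:
        lin, quad = study_day_terms(df[date_col])
        cols.append(lin)
        names.append("study_day")
        cols.append(quad)
        names.append("study_day_sq")
    return np.column_stack(cols), names


def _drop_aliased(X: np.ndarray, names: list[str]):
    """Drop linearly dependent columns (keeping earlier ones), with a warning."""
    if np.linalg.matrix_rank(X) == X.shape[1]:
        return X, names
    keep: list[int] = []
    for j in range(X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
        else:
            logger.warning("dropping aliased design column %s", names[j])
    return X[:, keep], [names[j] for j in keep]


def _filtered(df, outcome_col, spec, time_col, date_col):
    required = [outcome_col, time_col] + list(spec.categorical_covariates)
    if spec.detrend:
        required.append(date_col)
    missing = df[required].isna().any(axis=1)
    if missing.any():
        logger.info(
            "residualize: dropping %d rows with missing %s",
            int(missing.sum()),
            required,
        )
    out = df.loc[~missing]
    if len(out) == 0:
        raise ValueError("no rows remain after dropping missing values")
    return out, int(missing.sum())


def adjust_continuous(
    df: pd.DataFrame,
    outcome_col: str,
    spec: AdjustmentSpec,
    time_col: str = "local_hours",
    date_col: str = "local_date",
    reference_levels: dict | None = None,
) -> ResidualSeries:
    """OLS-residualize a continuous outcome on the adjustment design."""
    data, n_dropped = _filtered(df, outcome_col, spec, time_col, date_col)
    X, names = build_design(data, spec, date_col, reference_levels)
    X, names = _drop_aliased(X, names)
    y = data[outcome_col].to_numpy(dtype=float)
    resid = sm.OLS(y, X).fit().resid
    resid = np.asarray(resid)
    total_ss = float(np.sum((resid - resid.mean()) ** 2))
    series = ResidualSeries(
        residual=resid,
        time=data[time_col].to_numpy(dtype=float),
        n=len(resid),
        total_ss=total_ss,
        index=data.index,
    )
    return series


def adjust_binary(
    df: pd.DataFrame,
    outcome_col: str,
    spec: AdjustmentSpec,
    time_col: str = "local_hours",
    date_col: str = "local_date",
    reference_levels: dict | None = None,
) -> ResidualSeries:
    """Logit-residualize a 0/1 outcome; residuals are observed - fitted p."""
    data, _ = _filtered(df, outcome_col, spec, time_col, date_col)
    y = data[outcome_col].to_numpy(dtype=float)
    if not np.isin(y, [0.0, 1.0]).all():
        raise ValueError(f"binary outcome {outcome_col!r} must be coded 0/1")
    X, names = build_design(data, spec, date_col, reference_levels)
    X, names = _drop_aliased(X, names)
    # IRLS via GLM: tolerant of near-aliased dummy blocks where Newton's
    # exact Hessian goes singular
    import warnings as _warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("error", PerfectSeparationWarning)
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    except Exception as exc:  # separation surfaces as warning or error
        raise ValueError(
            f"logistic residualization failed: perfect separation suspected "
            f"among {names[1:]}: {exc}"
        ) from exc
    if not fit.converged:
        raise ValueError(
            f"logistic residualization did not converge (perfect separation "
            f"suspected among {names[1:]})"
        )
    resid = y - fit.predict(X)
    total_ss = float(np.sum((resid - resid.mean()) ** 2))
    return ResidualSeries(
        residual=resid,
        time=data[time_col].to_numpy(dtype=float),
        n=len(resid),
        total_ss=total_ss,
        index=data.index,
    )
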