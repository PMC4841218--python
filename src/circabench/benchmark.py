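"""Fixed-variable selection-effect benchmarks.

Age and gender cannot oscillate within a person over the day, so any
"rhythm" a cosinor finds in them must be a selection effect: different
people participating at different clock times.  Fitting the cosinor to
residualized age (OLS) and gender (logit, response residuals) therefore
yields a benchmark level of spurious variance-explained, against which the
outcome's rhythm is compared as a ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .cosinor import CosinorResults, fit_cosinor
from .residualize import AdjustmentSpec, adjust_binary, adjust_continuous


def benchmark_fixed_variable(
    df: pd.DataFrame,
    variable: str,
    kind: str,
    spec: AdjustmentSpec,
    time_col: str = "local_hours",
    date_col: str = "local_date",
) -> CosinorResults:
    """Residualize a fixed variable and fit the cosinor to its residuals.

    ``kind`` is ``"continuous"`` (OLS residuals) or ``"binary"`` (logit
    response residuals).  The variable must not appear among its own
    adjustment covariates.
    """
    if variable in spec.categorical_covariates:
        raise ValueError(
            f"benchmark variable {variable!r} is listed among its own "
            "adjustment covariates"
        )
    if kind == "continuous":
        series = adjust_continuous(df, variable, spec, time_col, date_col)
    elif kind == "binary":
        series = adjust_binary(df, variable, spec, time_col, date_col)
    else:
        raise ValueError(f"unknown benchmark kind {kind!r}")
    return fit_cosinor(series)


@dataclass
class BenchmarkReport:
    """Variance-explained comparison of outcome rhythm vs fixed variables."""

    r2_outcome_pct: float
    rows: list[dict] = field(default_factory=list)
    # each row: variable, r2_pct, acrophase_hours, ratio, ratio_infinite

    def to_dict(self) -> dict:
        return {
            "r2_outcome_pct": round(self.r2_outcome_pct, 4),
            "benchmarks": [
                {
                    "variable": r["variable"],
                    "r2_pct": round(r["r2_pct"], 4),
                    "acrophase_hours": r["acrophase_hours"],
                    "ratio": (None if r["ratio_infinite"]
                              else round(r["ratio"], 2)),
                    "ratio_infinite": r["ratio_infinite"],
                }
                for r in self.rows
            ],
        }

    def summary(self) -> str:
        lines = [
            "Selection-effect benchmark (variance explained by time of day)",
            f"  outcome r2 = {self.r2_outcome_pct:.4f}%",
        ]
        for r in self.rows:
            ratio = "inf" if r["ratio_infinite"] else f"{r['ratio']:.2f}"
            lines.append(
                f"  {r['variable']}: r2 = {r['r2_pct']:.4f}% "
                f"(x{ratio} the outcome's rhythm)"
            )
        return "\n".join(lines)


def benchmark_ratios(r2_outcome_pct: float, benchmark_r2: dict) -> BenchmarkReport:
    """Ratios r2(benchmark) / r2(outcome) for each fixed-variable benchmark.

    ``benchmark_r2`` maps variable name to either a bare r2 percentage or a
    (r2_pct, acrophase_hours) pair.  A zero outcome r2 flags the ratios as
    infinite rather than raising.
    """
    if r2_outcome_pct < 0:
        raise ValueError("r2_outcome_pct must be non-negative")
    rows = []
    for name, val in benchmark_r2.items():
        if isinstance(val, (tuple, list)):
            r2, acro = float(val[0]), float(val[1])
        else:
            r2, acro = float(val), math.nan
        if r2 < 0:
            raise ValueError(f"negative r2 for benchmark {name!r}")
        infinite = r2_outcome_pct == 0.0 and r2 > 0.0
        ratio = math.inf if infinite else (
            1.0 if r2 == r2_outcome_pct else r2 / r2_outcome_pct
        )
        rows.append(
            {
                "variable": name,
                "r2_pct": r2,
                "acrophase_hours": acro,
                "ratio": ratio,
                "ratio_infinite": infinite,
            }
        )
    return BenchmarkReport(r2_outcome_pct=r2_outcome_pct, rows=rows)
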