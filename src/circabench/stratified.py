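"""Per-age-year rhythm modelling and the acrophase-on-age regression.

Rather than assuming a functional form for how the rhythm's peak moves with
age, the cosinor is fitted separately within each year of age and the
predicted acrophase saved together with the number of contributing
observations.  A linear regression of acrophase on age, weighted by those
counts, then summarizes the gradient (reported in minutes per year).

Acrophases are clock times, so before the linear regression each stratum's
acrophase is unwrapped onto the 24-h branch closest to the circular mean
acrophase across strata; a rhythm peaking near midnight would otherwise
produce artificial 24-h jumps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cosinor import (Cosinor, ModerationResults, circular_diff_hours,
                      hours_to_hhmm, moderation_test)
from .residualize import ResidualSeries
from .timebase import PERIOD_HOURS, TWO_PI, wrap_hours

logger = logging.getLogger(__name__)


def acrophase_by_stratum(
    series: ResidualSeries,
    age,
    age_range: tuple[int, int] = (18, 89),
    min_n: int = 50,
) -> pd.DataFrame:
    """Fit one cosinor per year of age; return (age, acrophase, n) rows.

    Strata with fewer than ``min_n`` observations are dropped with a
    warning; if none remain, raises ValueError.
    """
    age = np.asarray(age)
    lo, hi = age_range
    rows = []
    for a in range(int(lo), int(hi) + 1):
        mask = age == a
        n = int(mask.sum())
        if n < max(min_n, 10):
            if n > 0:
                logger.warning(
                    "age stratum %d below minimum n (%d < %d); dropped",
                    a, n, min_n,
                )
            continue
        try:
            fit = Cosinor(series.residual[mask], series.time[mask]).fit()
        except ValueError as exc:
            logger.warning("age stratum %d skipped: %s", a, exc)
            continue
        rows.append(
            {
                "age": a,
                "acrophase_hours": fit.acrophase_hours,
                "acrophase_hhmm": fit.acrophase_hhmm,
                "n_obs": n,
            }
        )
    if not rows:
        raise ValueError("no age stratum meets the minimum observation count")
    return pd.DataFrame(rows)


def circular_mean_hours(hours, weights=None) -> float:
    """Circular mean of clock times in hours."""
    angles = TWO_PI * np.asarray(hours, dtype=float) / PERIOD_HOURS
    w = np.ones_like(angles) if weights is None else np.asarray(weights, float)
    s = np.sum(w * np.sin(angles))
    c = np.sum(w * np.cos(angles))
    if s == 0.0 and c == 0.0:
        raise ValueError("circular mean undefined for these values")
    return float(wrap_hours(PERIOD_HOURS / TWO_PI * np.arctan2(s, c)))


def unwrap_acrophases(hours, weights=None) -> np.ndarray:
    """Map clock-time acrophases onto the branch nearest their circular mean.

    The result is real-valued (can dip below 0 or above 24) but free of
    24-h discontinuities, making it safe to regress linearly.
    """
    hours = np.asarray(hours, dtype=float)
    center = circular_mean_hours(hours, weights)
    return center + np.array([circular_diff_hours(h, center) for h in hours])


@dataclass
class AcrophaseCurve:
    """Per-age acrophases with the weighted linear fit over them."""

    rows: pd.DataFrame  # columns: age, acrophase_hours, acrophase_hhmm, n_obs
    slope_min_per_year: float
    intercept_hours: float
    weighted_r2_pct: float
    f_stat: float
    df: tuple[int, int]
    p: float

    def predicted_acrophase(self, age) -> np.ndarray:
        return self.intercept_hours + (
            self.slope_min_per_year / 60.0
        ) * np.asarray(age, dtype=float)

    def summary(self) -> str:
        return (
            "Acrophase-by-age (weighted linear fit over per-year cosinors)\n"
            f"  strata = {len(self.rows)}, total n = "
            f"{int(self.rows['n_obs'].sum())}\n"
            f"  slope = {self.slope_min_per_year:+.3f} min/year, "
            f"intercept = {self.intercept_hours:.3f} h "
            f"({hours_to_hhmm(self.intercept_hours)})\n"
            f"  weighted r2 = {self.weighted_r2_pct:.2f}%, "
            f"F({self.df[0]}, {self.df[1]}) = {self.f_stat:.2f}, "
            f"p = {self.p:.3g}"
        )


def weighted_acrophase_regression(curve_rows: pd.DataFrame) -> AcrophaseCurve:
    """WLS of unwrapped acrophase on age, weights = contributing n.

    Requires at least 3 strata.  If all acrophases are identical the slope
    and r-squared are zero (not an error).
    """
    if len(curve_rows) < 3:
        raise ValueError("acrophase regression requires at least 3 age strata")
    ages = curve_rows["age"].to_numpy(dtype=float)
    w = curve_rows["n_obs"].to_numpy(dtype=float)
    phi = unwrap_acrophases(curve_rows["acrophase_hours"].to_numpy(), w)
    X = sm.add_constant(ages)
    res = sm.WLS(phi, X, weights=w).fit()
    if np.allclose(phi, phi[0]):
        slope, r2, f, p = 0.0, 0.0, 0.0, 1.0
        intercept = float(phi[0])
    else:
        intercept, slope = float(res.params[0]), float(res.params[1])
        r2 = float(res.rsquared)
        f = float(res.fvalue)
        p = float(res.f_pvalue)
    return AcrophaseCurve(
        rows=curve_rows.reset_index(drop=True),
        slope_min_per_year=slope * 60.0,
        intercept_hours=intercept,
        weighted_r2_pct=100.0 * r2,
        f_stat=f,
        df=(1, len(curve_rows) - 2),
        p=p,
    )


def continuous_age_moderation(
    series: ResidualSeries,
    age,
    age_range: tuple[int, int] = (18, 40),
) -> ModerationResults:
    """Sensitivity check: linear age entered directly into the cosinor.

    Restricts to the given age range, fits the continuous-moderator cosinor
    and reports the implied acrophases at the range endpoints along with
    their circular difference.
    """
    age = np.asarray(age, dtype=float)
    lo, hi = age_range
    mask = (age >= lo) & (age <= hi)
    sub = ResidualSeries(
        residual=series.residual[mask],
        time=series.time[mask],
        n=int(mask.sum()),
        total_ss=float(np.sum(
            (series.residual[mask] - series.residual[mask].mean()) ** 2
        )),
    )
    return moderation_test(
        sub, age[mask], kind="continuous",
        reference_values=[float(lo), float(hi)],
    )
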