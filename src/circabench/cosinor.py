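"""Single-component 24-hour cosinor regression and rhythm moderation.

The cosinor model

    y_i = M + A * cos(2*pi*(t_i - phi)/24) + e_i

is fitted through its linear decomposition

    y_i = M + beta_sin * sin(2*pi*t_i/24) + beta_cos * cos(2*pi*t_i/24) + e_i

by ordinary least squares, from which amplitude A = sqrt(beta_sin^2 +
beta_cos^2) and acrophase phi = (24/2pi) * atan2(beta_sin, beta_cos) mod 24
(the clock time at which the fitted wave peaks) are recovered.  Rhythm
strength is reported as the percentage of outcome variance explained by the
sine/cosine pair, with a joint Wald F-test of the two trigonometric
coefficients.

Moderation of the rhythm is tested by adding the moderator main effect(s)
and the two products sine x moderator and cosine x moderator, and jointly
testing the interaction block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .residualize import ResidualSeries
from .timebase import PERIOD_HOURS, TWO_PI, circular_encode, wrap_hours

logger = logging.getLogger(__name__)


def acrophase_from_coefs(beta_sin: float, beta_cos: float) -> float:
    """Clock time (hours, [0, 24)) at which the fitted cosine peaks.

    Uses the two-argument arctangent so the peak lands in the correct
    quadrant: a pure cosine (0, 1) peaks at midnight, a pure sine (1, 0)
    at 06:00.
    """
    if beta_sin == 0.0 and beta_cos == 0.0:
        raise ValueError("acrophase undefined: both coefficients are zero")
    return float(wrap_hours(PERIOD_HOURS / TWO_PI * np.arctan2(beta_sin, beta_cos)))


def circular_diff_hours(a: float, b: float) -> float:
    """Signed circular difference a - b in hours, wrapped into (-12, +12]."""
    return 12.0 - (12.0 - (a - b)) % PERIOD_HOURS


def hours_to_hhmm(hours: float) -> str:
    """Decimal hours to 'HH:MM' (rounded to the nearest minute, mod 24)."""
    total = int(round(wrap_hours(hours) * 60.0)) % (24 * 60)
    return f"{total // 60:02d}:{total % 60:02d}"


class Cosinor:
    """24-hour single-component cosinor model of an outcome on clock time.

    Parameters
    ----------
    endog : array-like
        Outcome values (typically residuals from covariate adjustment).
    times : array-like
        Local clock time in decimal hours; treated as circular with period
        24 h.

    ``fit()`` returns a :class:`CosinorResults`.
    """

    def __init__(self, endog, times):
        self.endog = np.asarray(endog, dtype=float)
        self.times = np.asarray(times, dtype=float)
        if self.endog.shape != self.times.shape:
            raise ValueError("endog and times must have the same length")
        if len(self.endog) < 10:
            raise ValueError("cosinor fit requires at least 10 observations")
        if len(np.unique(np.round(self.times, 9))) < 3:
            raise ValueError(
                "singular design: times must span at least 3 distinct values"
            )

    @classmethod
    def from_series(cls, series: ResidualSeries) -> "Cosinor":
        return cls(series.residual, series.time)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, outcome: str, time_col: str = "local_hours"
    ) -> "Cosinor":
        data = df[[outcome, time_col]].dropna()
        return cls(data[outcome].to_numpy(), data[time_col].to_numpy())

    def _design(self):
        s, c = circular_encode(self.times)
        return np.column_stack([np.ones_like(s), s, c])

    def fit(self) -> "CosinorResults":
        X = self._design()
        y = self.endog
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sse = float(resid @ resid)
        sst = float(np.sum((y - y.mean()) ** 2))
        n = len(y)
        dof = (2, n - 3)
        r2 = 0.0 if sst == 0.0 else max(0.0, 1.0 - sse / sst)
        if r2 >= 1.0:
            f_stat = np.inf
            p = 0.0
        else:
            f_stat = (r2 / 2.0) / ((1.0 - r2) / dof[1])
            p = float(stats.f.sf(f_stat, *dof))
        sigma2 = sse / dof[1] if dof[1] > 0 else np.nan
        xtx_inv = np.linalg.inv(X.T @ X)
        bse = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
        return CosinorResults(
            model=self,
            params=beta,
            bse=bse,
            nobs=n,
            sse=sse,
            sst=sst,
            r2_pct=100.0 * r2,
            f_stat=float(f_stat),
            df=dof,
            p=p,
        )


@dataclass
class CosinorResults:
    """Fitted cosinor: rhythm parameters, fit statistics and predictions."""

    model: Cosinor | None
    params: np.ndarray  # [mesor, beta_sin, beta_cos]
    bse: np.ndarray
    nobs: int
    sse: float
    sst: float
    r2_pct: float
    f_stat: float
    df: tuple[int, int]
    p: float

    @property
    def mesor(self) -> float:
        return float(self.params[0])

    @property
    def beta_sin(self) -> float:
        return float(self.params[1])

    @property
    def beta_cos(self) -> float:
        return float(self.params[2])

    @property
    def amplitude(self) -> float:
        return float(np.hypot(self.beta_sin, self.beta_cos))

    @property
    def acrophase_hours(self) -> float:
        return acrophase_from_coefs(self.beta_sin, self.beta_cos)

    @property
    def acrophase_hhmm(self) -> str:
        return hours_to_hhmm(self.acrophase_hours)

    def predict(self, times) -> np.ndarray:
        """Fitted curve M + A*cos(2*pi*(t - phi)/24) on a clock-time grid."""
        s, c = circular_encode(times)
        return self.mesor + self.beta_sin * s + self.beta_cos * c

    def to_dict(self) -> dict:
        return {
            "n": int(self.nobs),
            "mesor": self.mesor,
            "beta_sin": self.beta_sin,
            "beta_cos": self.beta_cos,
            "amplitude": self.amplitude,
            "acrophase_hours": self.acrophase_hours,
            "acrophase_hhmm": self.acrophase_hhmm,
            "r2_pct": self.r2_pct,
            "f_stat": self.f_stat,
            "df_num": self.df[0],
            "df_den": self.df[1],
            "p": self.p,
        }

    def summary(self) -> str:
        d = self.to_dict()
        lines = [
            "Cosinor regression (24-h single component)",
            f"  n = {d['n']}",
            f"  mesor      M   = {d['mesor']: .6f}",
            f"  amplitude  A   = {d['amplitude']: .6f}",
            f"  acrophase  phi = {d['acrophase_hours']:.3f} h "
            f"({d['acrophase_hhmm']})",
            f"  variance explained = {d['r2_pct']:.4f}%",
            f"  F({d['df_num']}, {d['df_den']}) = {d['f_stat']:.2f}, "
            f"p = {d['p']:.3g}",
        ]
        return "\n".join(lines)


def fit_cosinor(series, times=None) -> CosinorResults:
    """Fit the 24-h cosinor to a ResidualSeries or to (values, times)."""
    if isinstance(series, ResidualSeries):
        return Cosinor.from_series(series).fit()
    return Cosinor(series, times).fit()


def predict_curve(fit: CosinorResults, times) -> np.ndarray:
    return fit.predict(times)


class ModeratedCosinor:
    """Cosinor with sine x moderator and cosine x moderator interactions.

    For a categorical moderator with L retained levels the design holds the
    intercept, sine, cosine, L-1 level indicators and 2(L-1) interaction
    columns; the joint Wald F-test of the interaction block asks whether the
    rhythm's shape (amplitude and/or acrophase) differs across levels.  For a
    continuous moderator there are two interaction columns and the test has
    2 numerator df.
    """

    def __init__(self, endog, times, moderator, kind="categorical",
                 min_level_n=100):
        self.endog = np.asarray(endog, dtype=float)
        self.times = np.asarray(times, dtype=float)
        if kind not in ("categorical", "continuous"):
            raise ValueError(f"unknown moderator kind {kind!r}")
        self.kind = kind
        self.min_level_n = min_level_n
        if kind == "continuous":
            self.moderator = np.asarray(moderator, dtype=float)
            if np.ptp(self.moderator) == 0:
                raise ValueError("moderator is constant")
            self.levels = None
        else:
            mod = pd.Series(moderator)
            counts = mod.value_counts()
            if len(counts) < 2:
                raise ValueError("moderator is constant")
            keep = counts[counts >= min_level_n].index
            if len(keep) < 2:
                raise ValueError(
                    f"fewer than two moderator levels with >= {min_level_n} "
                    "observations"
                )
            dropped = sorted(set(counts.index) - set(keep))
            if dropped:
                logger.warning(
                    "moderation: dropping levels below min n=%d: %s",
                    min_level_n, dropped,
                )
            mask = mod.isin(keep).to_numpy()
            self.endog = self.endog[mask]
            self.times = self.times[mask]
            self.moderator = mod[mask].to_numpy()
            self.levels = sorted(keep)

    @classmethod
    def from_series(cls, series: ResidualSeries, moderator,
                    kind="categorical", min_level_n=100) -> "ModeratedCosinor":
        return cls(series.residual, series.time, moderator, kind, min_level_n)

    def _designs(self):
        s, c = circular_encode(self.times)
        base = [np.ones_like(s), s, c]
        if self.kind == "continuous":
            m = self.moderator
            main = [m]
            inter = [s * m, c * m]
        else:
            main, inter = [], []
            for lev in self.levels[1:]:
                d = (self.moderator == lev).astype(float)
                main.append(d)
                inter.append(s * d)
                inter.append(c * d)
        X_red = np.column_stack(base + main)
        X_full = np.column_stack(base + main + inter)
        return X_red, X_full, len(inter)

    def fit(self, reference_values=None) -> "ModerationResults":
        """Fit and test the interaction block.

        ``reference_values`` (continuous moderators only): moderator values
        at which to evaluate the implied per-value cosinor; defaults to the
        observed minimum and maximum.
        """
        X_red, X_full, q = self._designs()
        y = self.endog
        n = len(y)
        beta_f, _, rank_f, _ = np.linalg.lstsq(X_full, y, rcond=None)
        beta_r, _, _, _ = np.linalg.lstsq(X_red, y, rcond=None)
        sse_f = float(np.sum((y - X_full @ beta_f) ** 2))
        sse_r = float(np.sum((y - X_red @ beta_r) ** 2))
        sst = float(np.sum((y - y.mean()) ** 2))
        df_den = n - X_full.shape[1]
        f = max(0.0, (sse_r - sse_f) / q) / (sse_f / df_den)
        p = float(stats.f.sf(f, q, df_den))
        delta_r2_pct = 100.0 * max(0.0, sse_r - sse_f) / sst if sst > 0 else 0.0

        level_fits: dict = {}
        if self.kind == "categorical":
            for lev in self.levels:
                mask = self.moderator == lev
                level_fits[lev] = Cosinor(self.endog[mask],
                                          self.times[mask]).fit()
            keys = self.levels
        else:
            if reference_values is None:
                reference_values = [float(self.moderator.min()),
                                    float(self.moderator.max())]
            b0, bs, bc, bm, bsm, bcm = beta_f[:6]
            for v in reference_values:
                level_fits[v] = _implied_fit(
                    mesor=b0 + bm * v,
                    beta_sin=bs + bsm * v,
                    beta_cos=bc + bcm * v,
                    nobs=n,
                )
            keys = list(reference_values)
        shift = circular_diff_hours(
            level_fits[keys[-1]].acrophase_hours,
            level_fits[keys[0]].acrophase_hours,
        )
        return ModerationResults(
            joint_f=float(f),
            df=(q, df_den),
            p=p,
            delta_r2_pct=delta_r2_pct,
            level_fits=level_fits,
            acrophase_shift_hours=shift,
            kind=self.kind,
        )


def _implied_fit(mesor, beta_sin, beta_cos, nobs) -> CosinorResults:
    """CosinorResults carrying implied coefficients only (no fit stats)."""
    return CosinorResults(
        model=None,
        params=np.array([mesor, beta_sin, beta_cos]),
        bse=np.full(3, np.nan),
        nobs=nobs,
        sse=np.nan,
        sst=np.nan,
        r2_pct=np.nan,
        f_stat=np.nan,
        df=(2, nobs - 3),
        p=np.nan,
    )


@dataclass
class ModerationResults:
    """Joint interaction test plus per-level (or per-value) rhythm fits.

    ``acrophase_shift_hours`` is the signed circular difference between the
    last and first level's acrophase, wrapped into (-12, +12]; a negative
    value means the last level peaks earlier.
    """

    joint_f: float
    df: tuple[int, int]
    p: float
    delta_r2_pct: float
    level_fits: dict
    acrophase_shift_hours: float
    kind: str

    def to_dict(self) -> dict:
        return {
            "joint_f": self.joint_f,
            "df_num": self.df[0],
            "df_den": self.df[1],
            "p": self.p,
            "delta_r2_pct": self.delta_r2_pct,
            "acrophase_shift_hours": self.acrophase_shift_hours,
            "acrophase_shift_min": self.acrophase_shift_hours * 60.0,
            "levels": {
                str(k): {
                    "acrophase_hours": v.acrophase_hours,
                    "acrophase_hhmm": v.acrophase_hhmm,
                    "amplitude": v.amplitude,
                }
                for k, v in self.level_fits.items()
            },
        }

    def summary(self) -> str:
        lines = [
            "Rhythm moderation (joint sine/cosine interaction test)",
            f"  F({self.df[0]}, {self.df[1]}) = {self.joint_f:.2f}, "
            f"p = {self.p:.3g}, delta r2 = {self.delta_r2_pct:.4f}%",
        ]
        for k, v in self.level_fits.items():
            lines.append(
                f"  level {k!r}: acrophase {v.acrophase_hours:.3f} h "
                f"({v.acrophase_hhmm}), amplitude {v.amplitude:.5f}"
            )
        lines.append(
            f"  acrophase shift (last - first) = "
            f"{self.acrophase_shift_hours * 60.0:+.1f} min"
        )
        return "\n".join(lines)


def moderation_test(series, moderator, kind="categorical",
                    min_level_n=100, reference_values=None) -> ModerationResults:
    """Test moderation of the rhythm in a ResidualSeries by a moderator."""
    model = ModeratedCosinor.from_series(series, moderator, kind, min_level_n)
    return model.fit(reference_values=reference_values)
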