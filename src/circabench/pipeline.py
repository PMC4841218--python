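"""End-to-end analysis pipeline and report generation.

Orchestrates the full analysis: load or simulate records, convert server
timestamps to local clock time, exclude DST transition days, recode the
outcome to in-group preference, fit the adjusted and unadjusted rhythms
(part 1), test moderation by DST status, gender and age including the
per-age acrophase curve (part 2), and compare the outcome's rhythm against
fixed-variable selection benchmarks (part 3).  Emits one JSON report,
per-model CSVs, and a log of every exclusion count.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .benchmark import benchmark_fixed_variable, benchmark_ratios
from .cosinor import fit_cosinor, moderation_test
from .residualize import AdjustmentSpec, adjust_continuous
from .scoring import DEFAULT_REVERSE_GROUPS, recode_frame
from .simulate import PRESET_NAMES, scenario_preset, simulate
from .stratified import (acrophase_by_stratum, continuous_age_moderation,
                         weighted_acrophase_regression)
from .timebase import (default_zone_table, exclude_transition_days,
                       load_zone_table, localize_frame)

logger = logging.getLogger(__name__)

DEFAULT_COLUMNS = {
    "timestamp": "timestamp",
    "region_id": "region_id",
    "age": "age",
    "gender": "gender",
    "race": "race",
    "d_raw": "d_raw",
}


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_path`` and ``preset`` must be set.
    """

    input_path: str | None = None
    preset: str | None = None
    n: int = 200_000
    seed: int = 0
    column_mapping: dict = field(default_factory=lambda: dict(DEFAULT_COLUMNS))
    zone_csv: str | None = None
    dst_csv: str | None = None
    covariates: list[str] = field(
        default_factory=lambda: ["age", "gender", "race"]
    )
    detrend: bool = True
    moderators: list[str] = field(default_factory=lambda: ["is_dst", "gender"])
    age_range: tuple[int, int] = (18, 89)
    age_sensitivity_range: tuple[int, int] = (18, 40)
    min_stratum_n: int = 50
    min_level_n: int = 100
    benchmarks: dict = field(
        default_factory=lambda: {"age": "continuous", "gender": "binary"}
    )
    reverse_groups: tuple = tuple(sorted(DEFAULT_REVERSE_GROUPS))
    out_dir: str | None = None

    def __post_init__(self):
        if (self.input_path is None) == (self.preset is None):
            raise ValueError(
                "exactly one of input_path and preset must be set"
            )
        if self.preset is not None and self.preset not in PRESET_NAMES:
            raise ValueError(
                f"unknown preset {self.preset!r}; valid: "
                f"{', '.join(PRESET_NAMES)}"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Load from a YAML file.

        A bare ``preset: null`` means the preset *named* "null" (YAML would
        otherwise read the keyword as missing).
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "preset" in raw and raw["preset"] is None:
            raw["preset"] = "null"
        for key in ("age_range", "age_sensitivity_range", "reverse_groups"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def read_records(path, column_mapping=None) -> pd.DataFrame:
    """Read a delimiter-separated participant table into the pipeline schema.

    ``column_mapping`` maps standard names (timestamp, region_id, age,
    gender, race, d_raw) to the file's column names.  Rows with an
    unparseable timestamp or age are dropped with logged counts.
    """
    mapping = dict(DEFAULT_COLUMNS)
    mapping.update(column_mapping or {})
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"input file {path} contains no records")
    missing = [src for src in mapping.values() if src not in df.columns]
    if missing:
        raise ValueError(
            f"input file {path} is missing required column(s): {missing}"
        )
    df = df[[mapping[k] for k in mapping]].rename(
        columns={v: k for k, v in mapping.items()}
    )
    n0 = len(df)
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    age = pd.to_numeric(df["age"], errors="coerce")
    keep = ts.notna() & age.notna()
    n_bad = int((~keep).sum())
    if n_bad:
        logger.info("read_records: dropped %d of %d rows with unparseable "
                    "timestamp or age", n_bad, n0)
    df = df.loc[keep].copy()
    df["timestamp"] = ts.loc[keep]
    df["age"] = age.loc[keep].astype(int)
    df.attrs["n_dropped_unparseable"] = n_bad
    return df.reset_index(drop=True)


def _half_hour_bins(series) -> pd.DataFrame:
    """Observed residual means in half-hour clock-time bins (report parity)."""
    bins = np.floor(series.time * 2.0).astype(int)
    frame = pd.DataFrame({"bin": bins, "residual": series.residual})
    grp = frame.groupby("bin")["residual"].agg(["mean", "count"])
    grp = grp.reindex(range(48))
    return pd.DataFrame(
        {
            "bin_start_hours": np.arange(48) / 2.0,
            "mean_residual": grp["mean"].to_numpy(),
            "n": grp["count"].fillna(0).astype(int).to_numpy(),
        }
    )


def _stage(name):
    logger.info("pipeline stage: %s", name)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full three-part analysis; return the report dictionary.

    If ``config.out_dir`` is set, writes ``report.json``, per-model CSVs
    and ``run.log`` there.
    """
    exclusions: dict[str, int] = {}
    try:
        report = _run(config, exclusions)
    except Exception:
        logger.exception("pipeline halted")
        raise
    if config.out_dir:
        _write_outputs(report, config)
    return report


def _run(config: RunConfig, exclusions) -> dict:
    _stage("load")
    if config.preset is not None:
        sim = scenario_preset(config.preset, n=config.n, seed=config.seed)
        df = simulate(sim)
    else:
        df = read_records(config.input_path, config.column_mapping)
        exclusions["unparseable_rows"] = df.attrs.get("n_dropped_unparseable", 0)
    n_in = len(df)

    _stage("to_local_time")
    if config.zone_csv:
        zones = load_zone_table(config.zone_csv, config.dst_csv)
    else:
        years = pd.DatetimeIndex(df["timestamp"]).year
        zones = default_zone_table(range(int(years.min()), int(years.max()) + 2))
    df = localize_frame(df, zones)
    exclusions["unknown_zone"] = df.attrs.get("n_dropped_unknown_zone", 0)
    exclusions["bad_timestamp"] = df.attrs.get("n_dropped_bad_timestamp", 0)

    _stage("exclude_transition_days")
    df = exclude_transition_days(df, zones)
    exclusions["dst_transition_day"] = df.attrs.get("n_dropped_dst_transition", 0)

    _stage("recode_ingroup")
    df = recode_frame(df, reverse_groups=set(config.reverse_groups))
    exclusions["missing_race"] = df.attrs.get("n_dropped_missing_race", 0)

    spec = AdjustmentSpec(
        categorical_covariates=list(config.covariates), detrend=config.detrend
    )
    unadj_spec = AdjustmentSpec(categorical_covariates=[],
                                detrend=config.detrend)

    _stage("part1: cosinor fits")
    adjusted = adjust_continuous(df, "d_ingroup", spec)
    unadjusted = adjust_continuous(df, "d_ingroup", unadj_spec)
    fit_adj = fit_cosinor(adjusted)
    fit_unadj = fit_cosinor(unadjusted)

    _stage("part2: moderation")
    sub = df.loc[adjusted.index]
    moderation = {}
    for mod in config.moderators:
        try:
            moderation[mod] = moderation_test(
                adjusted, sub[mod].to_numpy(), kind="categorical",
                min_level_n=config.min_level_n,
            ).to_dict()
        except ValueError as exc:
            logger.warning("moderation by %s skipped: %s", mod, exc)
            moderation[mod] = {"error": str(exc)}

    age = sub["age"].to_numpy()
    curve_rows = acrophase_by_stratum(
        adjusted, age, config.age_range, config.min_stratum_n
    )
    curve = weighted_acrophase_regression(curve_rows)
    lo, hi = config.age_sensitivity_range
    age_sens = continuous_age_moderation(adjusted, age, (lo, hi))

    _stage("part3: fixed-variable benchmarks")
    bench_fits = {}
    for var, kind in config.benchmarks.items():
        covs = [c for c in config.covariates if c != var]
        bspec = AdjustmentSpec(categorical_covariates=covs,
                               detrend=config.detrend)
        frame = df
        if kind == "binary" and var == "gender":
            frame = df.assign(gender=(df["gender"] == "female").astype(int))
            covs = [c for c in config.covariates if c != "gender"]
            bspec = AdjustmentSpec(categorical_covariates=covs,
                                   detrend=config.detrend)
        bench_fits[var] = benchmark_fixed_variable(frame, var, kind, bspec)
    bench = benchmark_ratios(
        fit_adj.r2_pct,
        {v: (f.r2_pct, f.acrophase_hours) for v, f in bench_fits.items()},
    )

    total_excluded = sum(exclusions.values())
    report = {
        "meta": {
            "version": __version__,
            "seed": config.seed,
            "preset": config.preset,
            "input_path": config.input_path,
            "n_input": n_in,
            "n_analyzed": int(adjusted.n),
            "exclusions": exclusions,
            "records_accounted": n_in == len(df) + total_excluded,
        },
        "part1": {
            "adjusted": fit_adj.to_dict(),
            "unadjusted": fit_unadj.to_dict(),
        },
        "part2": {
            "moderation": moderation,
            "acrophase_by_age": {
                "slope_min_per_year": curve.slope_min_per_year,
                "intercept_hours": curve.intercept_hours,
                "weighted_r2_pct": curve.weighted_r2_pct,
                "f_stat": curve.f_stat,
                "df": list(curve.df),
                "p": curve.p,
                "n_strata": len(curve.rows),
            },
            "age_sensitivity_continuous": age_sens.to_dict(),
        },
        "part3": bench.to_dict(),
    }
    report["_artifacts"] = {
        "acrophase_curve": curve.rows,
        "binned_means": _half_hour_bins(adjusted),
        "fits": pd.DataFrame(
            [
                dict(model="adjusted", **fit_adj.to_dict()),
                dict(model="unadjusted", **fit_unadj.to_dict()),
                *(
                    dict(model=f"benchmark_{v}", **f.to_dict())
                    for v, f in bench_fits.items()
                ),
            ]
        ),
    }
    return report


def _write_outputs(report: dict, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts = report.pop("_artifacts", {})
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    for name, frame in artifacts.items():
        frame.to_csv(out / f"{name}.csv", index=False)
    with open(out / "run.log", "w") as fh:
        for key, count in report["meta"]["exclusions"].items():
            fh.write(f"excluded[{key}] = {count}\n")
        fh.write(f"n_input = {report['meta']['n_input']}\n")
        fh.write(f"n_analyzed = {report['meta']['n_analyzed']}\n")
    report["_artifacts"] = artifacts


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
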