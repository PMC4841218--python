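"""Local clock time, timezone offsets and daylight-saving handling.

Server timestamps are converted to local wall-clock time using an explicit
per-region zone table: a signed offset from the server zone (half-integer
offsets encode counties straddling two zones) plus, for DST-observing
regions, a table of DST intervals in local *standard* time.  Records falling
on a DST transition day are excluded from analysis, because wall-clock time
is ambiguous or skipped on those days.

Time of day is represented as decimal hours in [0, 24) and treated as
circular: the sine/cosine encoding used by the cosinor model lives here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TWO_PI = 2.0 * np.pi
PERIOD_HOURS = 24.0


def wrap_hours(hours):
    """Wrap decimal hours onto the circular domain [0, 24)."""
    return np.mod(hours, PERIOD_HOURS)


def circular_encode(t):
    """Return the (sin, cos) encoding of clock time ``t`` (decimal hours).

    The pair (sin(2*pi*t/24), cos(2*pi*t/24)) places each clock time on the
    unit circle, so midnight and 24:00 coincide and the cosinor design matrix
    treats time of day as periodic.
    """
    angle = TWO_PI * np.asarray(t, dtype=float) / PERIOD_HOURS
    return np.sin(angle), np.cos(angle)


def _nth_weekday(year: int, month: int, weekday: int, n: int) -> pd.Timestamp:
    """n-th given weekday (Mon=0) of a month, as a midnight Timestamp."""
    first = pd.Timestamp(year=year, month=month, day=1)
    shift = (weekday - first.dayofweek) % 7
    return first + pd.Timedelta(days=shift + 7 * (n - 1))


def us_dst_intervals(years) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """US DST intervals (local standard time) for the given years.

    From 2007 on: second Sunday of March 02:00 to first Sunday of November
    02:00.  2006 and earlier: first Sunday of April 02:00 to last Sunday of
    October 02:00.
    """
    out = []
    for year in sorted(set(int(y) for y in years)):
        if year >= 2007:
            start = _nth_weekday(year, 3, 6, 2) + pd.Timedelta(hours=2)
            # first Sunday of November
            end = _nth_weekday(year, 11, 6, 1) + pd.Timedelta(hours=2)
        else:
            start = _nth_weekday(year, 4, 6, 1) + pd.Timedelta(hours=2)
            last_oct = pd.Timestamp(year=year, month=10, day=31)
            end = (
                last_oct
                - pd.Timedelta(days=(last_oct.dayofweek - 6) % 7)
                + pd.Timedelta(hours=2)
            )
        out.append((start, end))
    return out


@dataclass
class ZoneSpec:
    """Offset (hours, may be half-integer) and DST rules for one region.

    ``offset_hours`` is the signed shift from the server clock to local
    standard time; a county spanning two zones is coded half-way between
    them, i.e. with a 0.5-h fractional offset.  ``dst_intervals`` are
    (start, end) pairs in local standard time; during an interval one hour
    is added to obtain wall-clock time.
    """

    region_id: str
    offset_hours: float
    observes_dst: bool = False
    dst_intervals: list[tuple[pd.Timestamp, pd.Timestamp]] = field(
        default_factory=list
    )

    def __post_init__(self):
        if not -12.0 <= self.offset_hours <= 12.0:
            raise ValueError(
                f"offset_hours {self.offset_hours} outside [-12, 12] "
                f"for region {self.region_id!r}"
            )
        ivals = sorted(self.dst_intervals)
        for (s1, e1), (s2, _) in zip(ivals, ivals[1:]):
            if s2 < e1:
                raise ValueError(
                    f"overlapping DST intervals for region {self.region_id!r}"
                )
        self.dst_intervals = ivals
        if self.observes_dst and not self.dst_intervals:
            raise ValueError(
                f"region {self.region_id!r} observes DST but has no intervals"
            )

    def dst_active(self, local_standard: pd.Series | pd.DatetimeIndex) -> np.ndarray:
        """Boolean mask: is DST in effect at these local *standard* times."""
        ts = pd.DatetimeIndex(local_standard)
        mask = np.zeros(len(ts), dtype=bool)
        if self.observes_dst:
            for start, end in self.dst_intervals:
                mask |= (ts >= start) & (ts < end)
        return mask

    def transition_dates(self) -> set:
        """Local calendar dates on which a DST transition occurs."""
        dates = set()
        if self.observes_dst:
            for start, end in self.dst_intervals:
                # start is in standard time; the end instant 02:00 standard is
                # 03:00 on the wall clock but the same calendar date.
                dates.add(start.normalize())
                dates.add((end + pd.Timedelta(hours=1)).normalize())
        return dates


def default_zone_table(years=range(2006, 2014)) -> dict[str, ZoneSpec]:
    """US-style zone table keyed by region_id, relative to the server zone.

    The server clock is taken as Eastern time; offsets are hours *behind*
    it.  ``central_east_split`` is a half-zone county coded half-way between
    Eastern and Central.  ``mountain_no_dst`` mimics Arizona.
    """
    ivals = us_dst_intervals(years)
    return {
        "eastern": ZoneSpec("eastern", 0.0, True, ivals),
        "central": ZoneSpec("central", -1.0, True, ivals),
        "mountain": ZoneSpec("mountain", -2.0, True, ivals),
        "pacific": ZoneSpec("pacific", -3.0, True, ivals),
        "central_east_split": ZoneSpec("central_east_split", -0.5, True, ivals),
        "mountain_no_dst": ZoneSpec("mountain_no_dst", -2.0, False),
    }


def load_zone_table(zone_csv, dst_csv=None) -> dict[str, ZoneSpec]:
    """Load a zone table from CSV.

    ``zone_csv``: columns region_id, offset_hours, observes_dst.
    ``dst_csv``: columns region_id, dst_start, dst_end (ISO-8601).
    """
    zones_df = pd.read_csv(zone_csv)
    intervals: dict[str, list] = {}
    if dst_csv is not None:
        dst_df = pd.read_csv(dst_csv, parse_dates=["dst_start", "dst_end"])
        for rid, grp in dst_df.groupby("region_id"):
            intervals[rid] = list(
                zip(grp["dst_start"], grp["dst_end"])
            )
    table = {}
    for row in zones_df.itertuples(index=False):
        rid = str(row.region_id)
        table[rid] = ZoneSpec(
            rid,
            float(row.offset_hours),
            bool(row.observes_dst),
            intervals.get(rid, []),
        )
    return table


def to_local_time(server_timestamp, zone: ZoneSpec):
    """Convert a server timestamp to local wall-clock time.

    Returns ``(clock_hours, local_date)`` where ``clock_hours`` is decimal
    hours in [0, 24) and ``local_date`` is the (possibly rolled) local
    calendar date.  Raises ValueError on an unparseable timestamp.
    """
    try:
        ts = pd.Timestamp(server_timestamp)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"malformed timestamp {server_timestamp!r}") from exc
    if pd.isna(ts):
        raise ValueError(f"malformed timestamp {server_timestamp!r}")
    standard = ts + pd.Timedelta(hours=zone.offset_hours)
    if zone.dst_active(pd.DatetimeIndex([standard]))[0]:
        local = standard + pd.Timedelta(hours=1)
    else:
        local = standard
    hours = (
        local.hour + local.minute / 60.0 + local.second / 3600.0
        + local.microsecond / 3.6e9
    )
    return wrap_hours(hours), local.normalize()


def localize_frame(
    df: pd.DataFrame,
    zones: dict[str, ZoneSpec],
    timestamp_col: str = "timestamp",
    region_col: str = "region_id",
) -> pd.DataFrame:
    """Vectorized server→local conversion over a record table.

    Adds columns ``local_hours`` (decimal, [0, 24)), ``local_date``
    (normalized Timestamp) and ``is_dst`` (bool).  Rows with a region_id
    absent from the zone table are dropped; the count is attached as
    ``result.attrs['n_dropped_unknown_zone']``.
    """
    ts = pd.to_datetime(df[timestamp_col], errors="coerce")
    bad_ts = ts.isna()
    known = df[region_col].isin(zones.keys())
    keep = known & ~bad_ts
    out = df.loc[keep].copy()
    ts = ts.loc[keep]

    local_hours = np.empty(len(out), dtype=float)
    local_date = np.empty(len(out), dtype="datetime64[ns]")
    is_dst = np.zeros(len(out), dtype=bool)
    pos = pd.Series(np.arange(len(out)), index=out.index)
    for rid, idx in out.groupby(region_col, observed=True).groups.items():
        zone = zones[rid]
        standard = pd.DatetimeIndex(ts.loc[idx]) + pd.Timedelta(
            hours=zone.offset_hours
        )
        dst = zone.dst_active(standard)
        local = standard + pd.to_timedelta(dst.astype(int), unit="h")
        p = pos.loc[idx].to_numpy()
        frac = (
            local.hour.to_numpy()
            + local.minute.to_numpy() / 60.0
            + local.second.to_numpy() / 3600.0
            + local.microsecond.to_numpy() / 3.6e9
        )
        local_hours[p] = frac
        local_date[p] = local.normalize().to_numpy()
        is_dst[p] = dst
    out["local_hours"] = wrap_hours(local_hours)
    out["local_date"] = local_date
    out["is_dst"] = is_dst
    out.attrs["n_dropped_unknown_zone"] = int((~known).sum())
    out.attrs["n_dropped_bad_timestamp"] = int((bad_ts & known).sum())
    return out


def exclude_transition_days(
    df: pd.DataFrame,
    zones: dict[str, ZoneSpec],
    region_col: str = "region_id",
    date_col: str = "local_date",
) -> pd.DataFrame:
    """Drop records whose local date is a DST transition day in their zone.

    Records in zones that do not observe DST are never removed; order is
    preserved.  The number removed is attached as
    ``result.attrs['n_dropped_dst_transition']``.
    """
    drop = np.zeros(len(df), dtype=bool)
    dates = pd.DatetimeIndex(df[date_col]).normalize()
    for rid, idx in df.groupby(region_col, observed=True).groups.items():
        zone = zones.get(rid)
        if zone is None or not zone.observes_dst:
            continue
        tdates = zone.transition_dates()
        if tdates:
            loc = df.index.get_indexer(idx)
            drop[loc] = dates[loc].isin(list(tdates))
    out = df.loc[~drop].copy()
    out.attrs = dict(df.attrs)
    out.attrs["n_dropped_dst_transition"] = int(drop.sum())
    return out
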