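"""Ingest, clean and hourly-regularize GPS trajectories.

Trajectories are kept as pandas DataFrames with one row per fix
(columns ``timestamp``, ``lon``, ``lat``, ``ground_speed``,
``solar_hour``); missing fixes carry a timestamp but NaN coordinates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo_time import geodesic_km, initial_bearing_rad, solar_hour

log = logging.getLogger(__name__)

#: Default Movebank export column names; override via ``aliases``.
MOVEBANK_COLUMNS = {
    "individual": "individual-local-identifier",
    "timestamp": "timestamp",
    "lon": "location-long",
    "lat": "location-lat",
    "ground_speed": "ground-speed",
}

#: Spring season window (month, day) inclusive.
SEASON_START = (2, 1)
SEASON_END = (7, 31)

#: Two fixes closer together than this are part of one burst (seconds).
BURST_WINDOW_S = 20.0

#: Snap tolerance for hourly regularization (minutes).
SNAP_TOLERANCE_MIN = 5.0


@dataclass
class Trajectory:
    """An individual-year point series, ordered by time."""

    individual_id: str
    year: int
    df: pd.DataFrame = field(repr=False)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_observed(self) -> int:
        """Number of fixes with known coordinates."""
        return int(self.df["lon"].notna().sum())

    def validate(self) -> None:
        ts = self.df["timestamp"]
        if not ts.is_monotonic_increasing or ts.duplicated().any():
            raise ValueError("timestamps must be strictly increasing")


def _season_year(ts: pd.Series) -> pd.Series:
    """Calendar year of the spring season each fix belongs to."""
    return ts.dt.year


def _in_season(ts: pd.Series) -> pd.Series:
    md = ts.dt.month * 100 + ts.dt.day
    lo = SEASON_START[0] * 100 + SEASON_START[1]
    hi = SEASON_END[0] * 100 + SEASON_END[1]
    return (md >= lo) & (md <= hi)


def read_movebank_csv(path, aliases: dict | None = None) -> list[Trajectory]:
    """Read a Movebank-style CSV into one ``Trajectory`` per individual-year.

    Rows with unparseable or empty coordinates are kept as missing
    fixes.  Fixes outside the spring season window (Feb 1 - Jul 31) are
    dropped.  Duplicate (individual, timestamp) rows raise.
    """
    cols = dict(MOVEBANK_COLUMNS)
    if aliases:
        cols.update(aliases)
    raw = pd.read_csv(path, dtype={cols["individual"]: str})
    missing_cols = [
        c for c in (cols["individual"], cols["timestamp"]) if c not in raw.columns
    ]
    if missing_cols:
        raise ValueError(f"mandatory columns absent: {missing_cols}")

    df = pd.DataFrame(
        {
            "individual_id": raw[cols["individual"]],
            "timestamp": pd.to_datetime(raw[cols["timestamp"]], utc=True).dt.tz_localize(
                None
            ),
            "lon": pd.to_numeric(raw.get(cols["lon"]), errors="coerce"),
            "lat": pd.to_numeric(raw.get(cols["lat"]), errors="coerce"),
            "ground_speed": pd.to_numeric(raw.get(cols["ground_speed"]), errors="coerce"),
        }
    )
    # a fix is missing only if *both* coordinates are unusable
    half = df["lon"].isna() ^ df["lat"].isna()
    df.loc[half, ["lon", "lat"]] = np.nan

    if df.duplicated(["individual_id", "timestamp"]).any():
        raise ValueError("duplicate (individual, timestamp) rows")

    df = df.sort_values(["individual_id", "timestamp"], kind="mergesort")
    df = df[_in_season(df["timestamp"])]
    df["year"] = _season_year(df["timestamp"])

    out = []
    for (ind, year), grp in df.groupby(["individual_id", "year"], sort=True):
        grp = grp.drop(columns=["individual_id", "year"]).reset_index(drop=True)
        grp["solar_hour"] = [
            solar_hour(t, lo) if np.isfinite(lo) else np.nan
            for t, lo in zip(grp["timestamp"], grp["lon"])
        ]
        out.append(Trajectory(str(ind), int(year), grp))
    return out


def clean_trajectory(t: Trajectory) -> Trajectory:
    """Drop the trailing zero-speed run and collapse GPS bursts.

    The maximal run of fixes with ground speed exactly 0 at the *end*
    of the track is removed (interior zero-speed fixes are kept).  Any
    fix within ``BURST_WINDOW_S`` seconds of the previously kept fix is
    part of a high-frequency burst and dropped; the first fix of each
    burst survives.
    """
    df = t.df.reset_index(drop=True)
    speed = df["ground_speed"].to_numpy()
    end = len(df)
    while end > 0 and speed[end - 1] == 0.0:
        end -= 1
    df = df.iloc[:end]
    if df.empty:
        raise ValueError(f"trajectory {t.individual_id}/{t.year} empty after cleaning")

    ts = df["timestamp"].to_numpy()
    keep = np.ones(len(df), dtype=bool)
    last_kept = ts[0]
    for i in range(1, len(df)):
        gap = (ts[i] - last_kept) / np.timedelta64(1, "s")
        if gap < BURST_WINDOW_S:
            keep[i] = False
        else:
            last_kept = ts[i]
    dropped = int((~keep).sum())
    if dropped:
        log.debug("%s/%s: dropped %d burst fixes", t.individual_id, t.year, dropped)
    return Trajectory(t.individual_id, t.year, df[keep].reset_index(drop=True))


def regularize_hourly(t: Trajectory) -> Trajectory:
    """Snap fixes to the hourly grid and fill gaps with missing fixes.

    Fixes within ``SNAP_TOLERANCE_MIN`` minutes of a whole hour are
    snapped to it; off-schedule fixes are dropped (logged).  When two
    fixes snap to the same hour the nearer one wins.  Every absent hour
    between the first and last snapped fix becomes a missing fix.
    Solar hour for missing fixes uses time-interpolated longitude, so
    the downstream state model has a covariate at every step.
    """
    df = t.df.reset_index(drop=True)
    ts = df["timestamp"]
    snapped = ts.dt.round("h")
    offset = (ts - snapped).abs()
    ok = offset <= pd.Timedelta(minutes=SNAP_TOLERANCE_MIN)
    n_off = int((~ok).sum())
    if n_off:
        log.debug("%s/%s: dropped %d off-schedule fixes", t.individual_id, t.year, n_off)
    df = df.assign(_hour=snapped, _offset=offset)[ok]
    if df.empty:
        raise ValueError("no fixes on the hourly schedule")
    # nearest fix wins within each hour slot
    dup = int(df["_hour"].duplicated().sum())
    if dup:
        log.debug("%s/%s: %d fixes lost to same-hour snaps", t.individual_id, t.year, dup)
    df = df.sort_values(["_hour", "_offset"], kind="mergesort").drop_duplicates(
        "_hour", keep="first"
    )
    df = df.sort_values("_hour", kind="mergesort")

    grid = pd.DataFrame(
        {"timestamp": pd.date_range(df["_hour"].iloc[0], df["_hour"].iloc[-1], freq="h")}
    )
    df = df.drop(columns=["timestamp", "_offset"]).rename(columns={"_hour": "timestamp"})
    out = grid.merge(df, on="timestamp", how="left")

    lon_interp = out["lon"].interpolate(method="linear", limit_direction="both")
    out["solar_hour"] = [
        solar_hour(ts_, lo) if np.isfinite(lo) else np.nan
        for ts_, lo in zip(out["timestamp"], lon_interp)
    ]
    return Trajectory(t.individual_id, t.year, out.reset_index(drop=True))


def compute_steps(t: Trajectory, model: str = "wgs84") -> pd.DataFrame:
    """Derive the observation stream for the movement state model.

    One row per inter-fix interval: ``sqrt_step`` (square root of the
    geodesic step length in km, NaN when either flanking fix is
    missing), ``turn_angle`` (signed heading change at the interval's
    start fix, radians in (-pi, pi], NaN for the first interval or when
    any of the three involved fixes is missing or a flanking step has
    zero length), and ``solar_hour`` at the interval start.
    """
    df = t.df
    if df["lon"].notna().sum() < 3:
        raise ValueError("need at least 3 located fixes to derive steps")
    lon = df["lon"].to_numpy()
    lat = df["lat"].to_numpy()
    n = len(df) - 1

    step = np.full(n, np.nan)
    bearing = np.full(n, np.nan)
    for i in range(n):
        if np.isfinite(lon[i]) and np.isfinite(lon[i + 1]):
            step[i] = geodesic_km((lon[i], lat[i]), (lon[i + 1], lat[i + 1]), model=model)
            if step[i] > 0.0:
                bearing[i] = initial_bearing_rad(
                    (lon[i], lat[i]), (lon[i + 1], lat[i + 1]), model=model
                )

    turn = np.full(n, np.nan)
    for i in range(1, n):
        if np.isfinite(bearing[i - 1]) and np.isfinite(bearing[i]):
            d = bearing[i] - bearing[i - 1]
            d = math.remainder(d, 2.0 * math.pi)  # -> [-pi, pi]
            if d <= -math.pi:  # sign convention: reversal is +pi
                d += 2.0 * math.pi
            if d == -math.pi:
                d = math.pi
            turn[i] = d

    return pd.DataFrame(
        {
            "sqrt_step": np.sqrt(step),
            "turn_angle": turn,
            "solar_hour": df["solar_hour"].to_numpy()[:n],
        }
    )
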