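"""Migration windows, staging-site segmentation and arrival events.

All distances here are geodesic kilometres; the threshold distance
``d_t`` is the distance a slow bird covers in one hour and separates
"same site" from "moved on".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

from .geo_time import geodesic_km, project_two_point, DEFAULT_ANCHORS
from .tracking import Trajectory

log = logging.getLogger(__name__)

#: Default migratory-flight cutoff date (month, day), inclusive.
ARRIVAL_CUTOFF = (6, 30)


@dataclass(frozen=True)
class MigrationWindow:
    start_location: tuple[float, float]
    end_location: tuple[float, float]
    start_time: pd.Timestamp
    end_time: pd.Timestamp

    def __post_init__(self):
        if self.start_time >= self.end_time:
            raise ValueError("start_time must precede end_time")


@dataclass
class StagingSite:
    site_id: int
    member_index: np.ndarray  # positional indices into the trajectory
    centroid: tuple[float, float]
    arrival_date: date
    departure_date: date


@dataclass
class ArrivalEvent:
    individual_year: tuple[str, int]
    site_id: int
    arrival_date: date
    arrival_doy: int
    location: tuple[float, float]
    projected: tuple[float, float] | None
    cum_distance_km: float


def threshold_distance(airspeed_mean: float, airspeed_sd: float) -> float:
    """Threshold distance d_t in km: one hour at (mean - 2 sd) airspeed."""
    eff = airspeed_mean - 2.0 * airspeed_sd
    if eff <= 0.0:
        raise ValueError("effective airspeed (mean - 2 sd) must be positive")
    return eff * 3600.0 / 1000.0


def find_endpoints(
    t: Trajectory, anchors=DEFAULT_ANCHORS
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Migration start and end locations of one individual-year.

    Start is the located fix with the minimum corridor-axis coordinate
    (two-point equidistant x) among February-April fixes; end the
    maximum among May-July fixes.  Ties go to the earlier fix.
    """
    df = t.df[t.df["lon"].notna()]
    month = df["timestamp"].dt.month
    early = df[(month >= 2) & (month <= 4)]
    late = df[(month >= 5) & (month <= 7)]
    if early.empty:
        raise ValueError("no located fixes in the February-April window")
    if late.empty:
        raise ValueError("no located fixes in the May-July window")

    def _extreme(sub: pd.DataFrame, minimum: bool):
        pts = list(zip(sub["lon"], sub["lat"]))
        x = np.array([p.x for p in project_two_point(pts, anchors)])
        best = np.min(x) if minimum else np.max(x)
        idx = int(np.flatnonzero(x == best)[0])  # rows are time-ordered
        return (float(sub["lon"].iloc[idx]), float(sub["lat"].iloc[idx]))

    return _extreme(early, True), _extreme(late, False)


def migration_window(
    t: Trajectory,
    start: tuple[float, float],
    end: tuple[float, float],
    d_t: float,
) -> MigrationWindow | None:
    """Bracket the migratory period by departure and arrival.

    ``start_time`` is the last fix within ``d_t`` of the start location
    before the final, permanent departure (no later fix up to the end
    arrival is within ``d_t`` of the start again).  ``end_time`` is the
    first fix within ``d_t`` of the end location.  Returns None when
    the individual never leaves the start's neighbourhood.
    """
    df = t.df[t.df["lon"].notna()].reset_index(drop=True)
    d_start = np.array(
        [geodesic_km((lo, la), start) for lo, la in zip(df["lon"], df["lat"])]
    )
    d_end = np.array(
        [geodesic_km((lo, la), end) for lo, la in zip(df["lon"], df["lat"])]
    )
    arrived = np.flatnonzero(d_end <= d_t)
    if len(arrived) == 0 or not np.any(d_start > d_t):
        return None
    i_end = int(arrived[0])
    near_start = np.flatnonzero(d_start[: i_end + 1] <= d_t)
    if len(near_start) == 0:
        return None
    i_start = int(near_start[-1])  # last time near start => departed for good
    if i_start >= i_end:
        return None
    return MigrationWindow(
        start_location=tuple(start),
        end_location=tuple(end),
        start_time=pd.Timestamp(df["timestamp"].iloc[i_start]),
        end_time=pd.Timestamp(df["timestamp"].iloc[i_end]),
    )


def segment_staging_sites(
    t: Trajectory,
    d_t: float,
    states: np.ndarray | None = None,
    exclude_states: tuple[int, ...] = (4,),
) -> list[StagingSite]:
    """Split non-migratory fixes into staging sites.

    ``states`` holds one decoded state per inter-fix interval (length
    ``len(t) - 1``); a fix is migratory if either adjacent interval is
    in ``exclude_states``.  A jump larger than ``d_t`` between
    temporally consecutive retained fixes opens a new site.  Missing
    fixes are ignored.
    """
    df = t.df.reset_index(drop=True)
    keep = df["lon"].notna().to_numpy()
    if states is not None:
        states = np.asarray(states)
        if len(states) != len(df) - 1:
            raise ValueError("states must have one entry per interval")
        migratory = np.isin(states, exclude_states)
        fix_mig = np.zeros(len(df), dtype=bool)
        fix_mig[:-1] |= migratory
        fix_mig[1:] |= migratory
        keep &= ~fix_mig
    idx = np.flatnonzero(keep)
    if len(idx) == 0:
        raise ValueError("no non-migratory located fixes to segment")

    lon = df["lon"].to_numpy()
    lat = df["lat"].to_numpy()
    groups: list[list[int]] = [[int(idx[0])]]
    for a, b in zip(idx[:-1], idx[1:]):
        d = geodesic_km((lon[a], lat[a]), (lon[b], lat[b]))
        if d > d_t:
            groups.append([])
        groups[-1].append(int(b))

    sites = []
    for sid, members in enumerate(groups, start=1):
        m = np.array(members)
        ts = df["timestamp"].iloc[m]
        sites.append(
            StagingSite(
                site_id=sid,
                member_index=m,
                centroid=(float(lon[m].mean()), float(lat[m].mean())),
                arrival_date=ts.iloc[0].date(),
                departure_date=ts.iloc[-1].date(),
            )
        )
    return sites


def extract_arrival_events(
    sites: list[StagingSite],
    t: Trajectory,
    start: tuple[float, float],
    d_t: float,
    cutoff: tuple[int, int] = ARRIVAL_CUTOFF,
    anchors=DEFAULT_ANCHORS,
) -> list[ArrivalEvent]:
    """Arrival events at staging sites, filtered and annotated.

    Sites whose centroid lies within ``d_t`` of the start location are
    dropped, as are arrivals after the cutoff date (June 30 itself is
    kept).  Cumulative distance runs over the surviving events from the
    start location.
    """
    cutoff_date = date(t.year, cutoff[0], cutoff[1])
    events = []
    prev = tuple(start)
    cum = 0.0
    ordered = sorted(sites, key=lambda s: s.arrival_date)
    for s in ordered:
        if geodesic_km(s.centroid, start) <= d_t:
            continue
        if s.arrival_date > cutoff_date:
            continue
        cum += geodesic_km(prev, s.centroid)
        prev = s.centroid
        proj = project_two_point([s.centroid], anchors)[0]
        events.append(
            ArrivalEvent(
                individual_year=(t.individual_id, t.year),
                site_id=s.site_id,
                arrival_date=s.arrival_date,
                arrival_doy=s.arrival_date.timetuple().tm_yday,
                location=s.centroid,
                projected=(proj.x, proj.y),
                cum_distance_km=cum,
            )
        )
    return events


def events_to_frame(events: list[ArrivalEvent]) -> pd.DataFrame:
    """Tabulate arrival events (one row per event)."""
    return pd.DataFrame(
        {
            "individual_id": [e.individual_year[0] for e in events],
            "year": [e.individual_year[1] for e in events],
            "site_id": [e.site_id for e in events],
            "arrival_date": [e.arrival_date for e in events],
            "arrival_doy": [e.arrival_doy for e in events],
            "lon": [e.location[0] for e in events],
            "lat": [e.location[1] for e in events],
            "proj_x": [e.projected[0] if e.projected else np.nan for e in events],
            "proj_y": [e.projected[1] if e.projected else np.nan for e in events],
            "cum_distance_km": [e.cum_distance_km for e in events],
        }
    )
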