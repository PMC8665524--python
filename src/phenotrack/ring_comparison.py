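"""Passage timing of tracked birds versus ring-recovery climatology.

Longitudinal bands are half-open 10-degree intervals [lo, lo + 10) of
*geographic* longitude spanning 0-80 degrees east.  Ring recoveries in
the spring window give per-scheme band means; tracked birds' first
crossings of each band's lower edge are compared against those means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

from .arrival_model import LmmFit, LmmSpec, fit_gaussian_lmm

log = logging.getLogger(__name__)

BAND_EDGES = tuple(range(0, 80, 10))
BAND_WIDTH = 10.0

#: Default spring window for ring recoveries, (month, day) inclusive.
SPRING_WINDOW = ((2, 1), (6, 30))

RING_COLUMNS = ("scheme", "ring_id", "event_type", "date", "lon", "lat")


def band_of(lon: float) -> int | None:
    """Lower edge of the band containing ``lon``, or None outside 0-80E."""
    if lon < BAND_EDGES[0] or lon >= BAND_EDGES[-1] + BAND_WIDTH:
        return None
    return int((lon // BAND_WIDTH) * BAND_WIDTH)


@dataclass(frozen=True)
class BandSummary:
    scheme: str
    band: int
    mean_doy: float
    sd_doy: float
    n: int


def read_ring_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("scheme", "date", "lon") if c not in df.columns]
    if missing:
        raise ValueError(f"ring CSV lacks columns {missing}")
    df["date"] = pd.to_datetime(df["date"])
    return df


def band_passage_summary(
    recoveries: pd.DataFrame,
    spring_window=SPRING_WINDOW,
    include_control_points: bool = False,
) -> list[BandSummary]:
    """Mean and s.d. of spring recovery DOY per scheme and band.

    Recoveries outside the spring window or the 0-80E band span are
    ignored; marked-in-spring control points (``event_type ==
    "control"``) only enter when requested.  Empty cells are simply
    absent from the result.
    """
    df = recoveries.copy()
    if "event_type" in df.columns and not include_control_points:
        df = df[df["event_type"] != "control"]
    ts = pd.to_datetime(df["date"])
    md = ts.dt.month * 100 + ts.dt.day
    (m0, d0), (m1, d1) = spring_window
    df = df[(md >= m0 * 100 + d0) & (md <= m1 * 100 + d1)]
    df = df.assign(doy=pd.to_datetime(df["date"]).dt.dayofyear)
    df["band"] = [band_of(lo) for lo in df["lon"]]
    df = df[df["band"].notna()]

    out = []
    for (scheme, band), grp in df.groupby(["scheme", "band"], sort=True):
        out.append(
            BandSummary(
                scheme=str(scheme),
                band=int(band),
                mean_doy=float(grp["doy"].mean()),
                sd_doy=float(grp["doy"].std(ddof=1)) if len(grp) > 1 else 0.0,
                n=int(len(grp)),
            )
        )
    return out


def first_band_crossings(events: pd.DataFrame) -> dict[int, date]:
    """Date of the first arrival event at or beyond each band's lower edge.

    ``events`` holds one individual-year's arrival events with ``lon``
    (geographic) and ``arrival_date``; bands never surpassed are absent
    from the mapping.
    """
    ev = events.sort_values("arrival_date")
    out: dict[int, date] = {}
    for edge in BAND_EDGES:
        beyond = ev[ev["lon"] >= edge]
        if not beyond.empty:
            when = beyond["arrival_date"].iloc[0]
            if isinstance(when, pd.Timestamp):
                when = when.date()
            out[edge] = when
    return out


def delta_arrival_ring(
    crossings: dict[tuple[str, int], dict[int, date]],
    summaries: list[BandSummary],
) -> pd.DataFrame:
    """Tracked-minus-reference passage delays.

    ``crossings`` maps (individual_id, year) to that bird's band
    crossing dates.  One row per (individual-year, band, scheme) with a
    defined band mean.
    """
    by_key = {(s.scheme, s.band): s for s in summaries}
    schemes = sorted({s.scheme for s in summaries})
    rows = []
    for (ind, year), bands in crossings.items():
        for band, when in bands.items():
            doy = when.timetuple().tm_yday
            for scheme in schemes:
                ref = by_key.get((scheme, band))
                if ref is None:
                    continue
                rows.append(
                    {
                        "individual_id": ind,
                        "year": year,
                        "band": band,
                        "scheme": scheme,
                        "tracked_doy": doy,
                        "reference_doy": ref.mean_doy,
                        "delay_days": doy - ref.mean_doy,
                    }
                )
    return pd.DataFrame(rows)


def fit_ring_model(delays: pd.DataFrame, extra_terms: tuple[str, ...] = ()) -> LmmFit:
    """Mixed model of tracking delay: scheme means + scheme:longitude.

    Fixed effects are cell-means intercepts per ringing scheme and a
    per-scheme slope on band longitude (z-scored band centre); a random
    intercept per individual-year absorbs repeated measurements.
    ``extra_terms`` may add droppable covariate columns of ``delays``
    (e.g. sex, capture site, TGS deviation) as plain linear terms.
    """
    if delays["scheme"].nunique() < 2:
        raise ValueError("need delays for at least two schemes")
    df = delays.copy()
    centre = df["band"].to_numpy(dtype=float) + BAND_WIDTH / 2.0
    sd = centre.std() if centre.std() > 0 else 1.0
    lon_scaled = (centre - centre.mean()) / sd

    schemes = sorted(df["scheme"].unique())
    cols, names = [], []
    for s in schemes:
        ind = (df["scheme"] == s).to_numpy(dtype=float)
        cols.append(ind)
        names.append(f"intercept[{s}]")
    for s in schemes:
        ind = (df["scheme"] == s).to_numpy(dtype=float)
        cols.append(ind * lon_scaled)
        names.append(f"longitude[{s}]")
    for term in extra_terms:
        cols.append(df[term].to_numpy(dtype=float))
        names.append(term)

    idy = np.array([f"{i}/{y}" for i, y in zip(df["individual_id"], df["year"])])
    spec = LmmSpec(include_individual_year=False, include_ou=False)
    return fit_gaussian_lmm(
        df["delay_days"].to_numpy(dtype=float),
        np.column_stack(cols),
        names,
        individual=idy,  # random intercept per individual-year
        individual_year=idy,
        spec=spec,
    )
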