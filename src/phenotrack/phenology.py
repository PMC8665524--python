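"""Thermal-growing-season phenology from hourly gridded 2-m temperature.

The onset of the thermal growing season (TGS) is, by default, located
with a degree-day-sum criterion: take the within-year cumulative sum of
(daily mean - reference temperature) and call onset the day after that
sum attains its minimum.  This is robust against isolated warm days.  A
persistence rule (first day of a run of warm days) is available as an
alternative.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .geo_time import geodesic_km

log = logging.getLogger(__name__)

#: Reference temperature for the thermal growing season, deg C.
T_REF = 5.0

#: Climatology period (inclusive) for the mean TGS onset.
CLIMATOLOGY_YEARS = (1998, 2017)

#: Minimum hourly coverage for a daily mean.
MIN_HOURS_PER_DAY = 20


def open_temperature(path, var: str | None = None) -> xr.DataArray:
    """Open an hourly 2-m temperature NetCDF as a (time, lat, lon) array.

    Kelvin values (> 100) are converted to Celsius with a log note.
    """
    ds = xr.open_dataset(path)
    if var is None:
        candidates = [v for v in ds.data_vars if ds[v].ndim == 3]
        if len(candidates) != 1:
            raise ValueError(
                f"cannot pick a temperature variable from {list(ds.data_vars)}"
            )
        var = candidates[0]
    da = ds[var]
    if float(da.max()) > 100.0:
        log.info("temperature values > 100: assuming Kelvin, converting to Celsius")
        da = da - 273.15
    return da


def daily_mean_temperature(hourly: xr.DataArray) -> xr.DataArray:
    """Per-cell daily mean temperature in deg C (UTC days).

    Days with fewer than ``MIN_HOURS_PER_DAY`` hourly values become NaN.
    """
    grouped = hourly.resample(time="1D")
    mean = grouped.mean()
    count = hourly.notnull().resample(time="1D").sum()
    return mean.where(count >= MIN_HOURS_PER_DAY)


#: Last candidate day (DOY) for the onset search: onsets are a
#: first-half-of-year phenomenon; without this bound the cold autumn
#: tail can dominate the cumulative sum.
ONSET_SEARCH_END_DOY = 182


def tgs_onset(
    daily: np.ndarray | pd.Series,
    t_ref: float = T_REF,
    rule: str = "degree_day_sum",
    persistence_days: int = 5,
    search_end_doy: int = ONSET_SEARCH_END_DOY,
) -> float:
    """TGS onset day of year for one cell-year, or NaN if undefined.

    ``daily`` holds the daily mean temperatures of a full calendar year
    (index 0 = DOY 1).  Under the default ``degree_day_sum`` rule the
    onset is the day after the minimum of ``cumsum(daily - t_ref)``
    over boundaries up to ``search_end_doy`` (minimum before day 1
    gives onset DOY 1); a sum still falling at the end of the search
    window, or a year that never rises above ``t_ref``, is undefined.
    The ``persistence`` rule returns the first day opening a run of
    ``persistence_days`` consecutive days above ``t_ref``.  Missing
    days at or after the candidate onset (within the search window)
    make the result undefined.
    """
    x = np.asarray(daily, dtype=float)
    if len(x) not in (365, 366):
        raise ValueError("daily series must cover a full calendar year")
    if not np.any(x > t_ref):
        return float("nan")

    if rule == "degree_day_sum":
        end = min(len(x), search_end_doy)
        window = x[:end]
        missing = np.isnan(window)
        filled = np.where(missing, t_ref, window)  # neutral fill to locate argmin
        s = np.concatenate([[0.0], np.cumsum(filled - t_ref)])
        onset = int(np.argmin(s)) + 1  # first minimum wins on ties
        if onset > end:
            return float("nan")
        if missing[onset - 1 :].any():
            warnings.warn("missing days span the candidate TGS onset")
            return float("nan")
        return float(onset)

    if rule == "persistence":
        warm = x > t_ref
        warm_filled = np.where(np.isnan(x), False, warm)
        run = 0
        for i, w in enumerate(warm_filled):
            run = run + 1 if w else 0
            if run >= persistence_days:
                onset = i - persistence_days + 2  # 1-based first day of the run
                if np.any(np.isnan(x[onset - 1 : i + 1])):
                    warnings.warn("missing days span the candidate TGS onset")
                    return float("nan")
                return float(onset)
        return float("nan")

    raise ValueError(f"unknown onset rule {rule!r}")


def tgs_climatology(onsets: dict[int, float] | pd.Series) -> float:
    """Mean TGS onset over the defined years of the climatology period."""
    s = pd.Series(onsets, dtype=float).dropna()
    if s.empty:
        raise ValueError("no defined yearly onsets")
    return float(s.mean())


def tgs_deviation(onset_year: float, tgs_mean: float) -> float:
    """Signed deviation of one year's onset from the climatology, days."""
    if not (np.isfinite(onset_year) and np.isfinite(tgs_mean)):
        raise ValueError("both onset and climatology must be defined")
    return float(onset_year - tgs_mean)


def growing_degree_days(
    daily: np.ndarray | pd.Series,
    t_ref: float = T_REF,
    from_doy: int = 1,
    to_doy: int | None = None,
) -> float:
    """Degree days accumulated over ``[from_doy, to_doy)``.

    Sum of ``max(0, daily - t_ref)`` over the half-open day range;
    negative exceedances contribute zero.  Missing days in range yield
    NaN with a warning.
    """
    x = np.asarray(daily, dtype=float)
    if to_doy is None:
        to_doy = len(x) + 1
    if from_doy > to_doy:
        raise ValueError("from_doy must not exceed to_doy")
    window = x[from_doy - 1 : to_doy - 1]
    if np.any(np.isnan(window)):
        warnings.warn("missing days inside the GDD window")
        return float("nan")
    return float(np.sum(np.clip(window - t_ref, 0.0, None)))


@dataclass
class PhenologyGrid:
    """Per-cell TGS onset, climatology, deviation and daily series.

    ``onset`` is a DataArray (year, latitude, longitude) of onset DOYs,
    ``mean`` the climatological mean onset per cell, ``deviation`` the
    per-year signed deviation, and ``daily`` the daily mean temperature
    used to derive them (kept for GDD queries).
    """

    onset: xr.DataArray
    mean: xr.DataArray
    deviation: xr.DataArray
    daily: xr.DataArray
    t_ref: float = T_REF

    @classmethod
    def from_hourly(
        cls,
        hourly: xr.DataArray,
        t_ref: float = T_REF,
        rule: str = "degree_day_sum",
        climatology_years: tuple[int, int] = CLIMATOLOGY_YEARS,
    ) -> "PhenologyGrid":
        daily = daily_mean_temperature(hourly)
        years = np.unique(daily["time"].dt.year.values)
        lat = daily["latitude"].values
        lon = daily["longitude"].values
        onset = np.full((len(years), len(lat), len(lon)), np.nan)
        for yi, y in enumerate(years):
            block = daily.sel(time=str(y))
            vals = block.values  # (days, lat, lon)
            if vals.shape[0] not in (365, 366):
                continue
            for li in range(len(lat)):
                for lo in range(len(lon)):
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        onset[yi, li, lo] = tgs_onset(vals[:, li, lo], t_ref, rule)
        onset_da = xr.DataArray(
            onset,
            coords={"year": years, "latitude": lat, "longitude": lon},
            dims=("year", "latitude", "longitude"),
        )
        y0, y1 = climatology_years
        clim = onset_da.sel(year=slice(y0, y1))
        mean = clim.mean(dim="year", skipna=True)
        deviation = onset_da - mean
        return cls(onset_da, mean, deviation, daily, t_ref)

    def nearest_cell(self, lon: float, lat: float) -> tuple[int, int]:
        """Indices of the grid cell whose centre is nearest (great circle).

        Equidistant candidates resolve to the lower flat index.
        """
        lats = self.onset["latitude"].values
        lons = self.onset["longitude"].values
        best, best_d = (0, 0), np.inf
        for li, la in enumerate(lats):
            for lo, ln in enumerate(lons):
                d = geodesic_km((lon, lat), (float(ln), float(la)), model="sphere")
                if d < best_d - 1e-9:
                    best, best_d = (li, lo), d
        return best

    def annotate(self, lon: float, lat: float, year: int) -> dict:
        """Onset, deviation and daily series of the nearest cell-year."""
        li, lo = self.nearest_cell(lon, lat)
        res = {
            "onset": float(self.onset.sel(year=year).values[li, lo])
            if year in self.onset["year"].values
            else float("nan"),
            "mean": float(self.mean.values[li, lo]),
        }
        res["deviation"] = (
            res["onset"] - res["mean"]
            if np.isfinite(res["onset"]) and np.isfinite(res["mean"])
            else float("nan")
        )
        try:
            block = self.daily.sel(time=str(year))
            res["daily"] = block.values[:, li, lo]
        except KeyError:
            res["daily"] = None
        return res

    def to_dataframe(self) -> pd.DataFrame:
        df = self.onset.to_dataframe(name="tgs_onset").reset_index()
        mean = self.mean.to_dataframe(name="tgs_mean").reset_index()
        df = df.merge(mean, on=["latitude", "longitude"])
        df["tgs_deviation"] = df["tgs_onset"] - df["tgs_mean"]
        return df
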