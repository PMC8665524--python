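"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of ``(config, seed)`` and returns its
output together with a ground-truth record, so downstream operations
can be tested without any data downloads.  Identical seeds give
identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .geo_time import geodesic_km
from .movement_hmm import HmmParams
from .tracking import Trajectory

_KM_PER_DEG_LAT = 111.32


def _default_hmm_params() -> HmmParams:
    """Well-separated 4-state parameters on the sqrt-km scale.

    Means span resting (~10 m) to migratory flight (~70 km/h).
    """
    S = 4
    beta = np.zeros((S, S, 3))
    beta[..., 0] = -2.5
    return HmmParams(
        step_mean=np.array([0.1, 0.7, 2.2, 8.4]),
        step_sd=np.array([0.05, 0.3, 0.7, 1.2]),
        step_zero_mass=np.array([0.3, 0.02, 0.0, 0.0]),
        angle_shape=np.array([1.0, 1.0, 1.3, 0.6]),
        angle_scale=np.array([1.5, 1.5, 1.2, 0.3]),
        beta=beta,
        delta=np.full(S, 0.25),
    )


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryConfig:
    """Planted itinerary for a synthetic hourly track.

    ``sites`` are visited in order; consecutive sites must be at least
    ``2 * d_t`` apart so the segmentation ground truth is unambiguous.
    """

    sites: tuple = ((10.0, 53.0), (14.0, 55.0), (19.0, 57.0))
    dwell_hours: int = 96
    d_t: float = 50.184
    wander_km: float = 8.0  # within-site wander radius (<= d_t / 4)
    leg_speed_kmh: float = 65.0
    state_probs: tuple = (0.5, 0.35, 0.15)  # dwell mix of states 1-3
    missing_rate: float = 0.0
    start: str = "2018-03-01T00:00:00"
    individual_id: str = "syn-001"
    hmm: HmmParams = field(default_factory=_default_hmm_params)


def _move(lon, lat, km, bearing):
    dlat = km * math.cos(bearing) / _KM_PER_DEG_LAT
    dlon = km * math.sin(bearing) / (_KM_PER_DEG_LAT * math.cos(math.radians(lat)))
    return lon + dlon, lat + dlat


def simulate_trajectory(
    config: TrajectoryConfig | None = None, seed: int = 0
) -> tuple[Trajectory, dict]:
    """Hourly track over a planted staging itinerary, with truth.

    Within-site hours draw a behavioural state from ``state_probs``
    (states 1-3) and a step from that state's gamma emission, bounded
    by the wander radius; migration legs move at ``leg_speed_kmh``
    toward the next site in state 4.  The truth record holds the state
    of every interval, the itinerary, and per-site arrival dates
    (first observed non-migratory fix at the site).
    """
    cfg = config or TrajectoryConfig()
    for a, b in zip(cfg.sites[:-1], cfg.sites[1:]):
        if geodesic_km(a, b) < 2.0 * cfg.d_t:
            raise ValueError("itinerary sites closer than 2 * d_t")
    rng = np.random.default_rng(seed)
    p = cfg.hmm

    lons, lats, states = [], [], []
    lon, lat = cfg.sites[0]
    lons.append(lon), lats.append(lat)
    site_first_fix: dict[int, int] = {0: 0}

    for si, site in enumerate(cfg.sites):
        if si > 0:
            # migration leg toward this site
            while geodesic_km((lon, lat), site) > cfg.leg_speed_kmh:
                brg = _bearing(lon, lat, *site) + rng.normal(0.0, 0.05)
                km = cfg.leg_speed_kmh * math.exp(rng.normal(0.0, 0.08))
                lon, lat = _move(lon, lat, km, brg)
                lons.append(lon), lats.append(lat), states.append(4)
            lon, lat = site
            lons.append(lon), lats.append(lat), states.append(4)
            site_first_fix[si] = len(lons) - 1
        # dwell at the site
        for _ in range(cfg.dwell_hours):
            s = int(rng.choice(3, p=np.asarray(cfg.state_probs)))
            if rng.random() < p.step_zero_mass[s]:
                km = 0.0
            else:
                shape = (p.step_mean[s] / p.step_sd[s]) ** 2
                scale = p.step_sd[s] ** 2 / p.step_mean[s]
                km = float(rng.gamma(shape, scale)) ** 2
            km = min(km, cfg.wander_km / 2.0)
            away = geodesic_km((lon, lat), site)
            if away > cfg.wander_km:
                brg = _bearing(lon, lat, *site)  # head back in
            else:
                brg = rng.uniform(-math.pi, math.pi)
            lon, lat = _move(lon, lat, km, brg)
            lons.append(lon), lats.append(lat), states.append(s + 1)

    n = len(lons)
    ts = pd.date_range(cfg.start, periods=n, freq="h")
    lons_a, lats_a = np.array(lons), np.array(lats)
    observed = np.ones(n, dtype=bool)
    if cfg.missing_rate > 0:
        interior = rng.random(n) < cfg.missing_rate
        interior[0] = interior[-1] = False
        observed = ~interior
    lons_obs = np.where(observed, lons_a, np.nan)
    lats_obs = np.where(observed, lats_a, np.nan)
    from .geo_time import solar_hour

    df = pd.DataFrame(
        {
            "timestamp": ts,
            "lon": lons_obs,
            "lat": lats_obs,
            "ground_speed": np.where(np.array([0] + states) == 1, 0.0, 5.0),
            "solar_hour": [
                solar_hour(t, lo) if np.isfinite(lo) else np.nan
                for t, lo in zip(ts, np.where(observed, lons_a, np.interp(
                    np.arange(n), np.flatnonzero(observed), lons_a[observed])))
            ],
        }
    )
    traj = Trajectory(cfg.individual_id, int(ts[0].year), df)

    states_arr = np.array(states)  # one state per interval

    def _nonmigratory_fix(j: int) -> bool:
        if not observed[j]:
            return False
        if j > 0 and states_arr[j - 1] == 4:
            return False
        if j < n - 1 and states_arr[j] == 4:
            return False
        return True

    arrival_dates = {}
    for si, i0 in site_first_fix.items():
        # first observed fix at the site not flanked by a migratory interval
        j = i0
        while j < n - 1 and not _nonmigratory_fix(j):
            j += 1
        arrival_dates[si] = ts[j].date()

    truth = {
        "states": states_arr,
        "sites": list(cfg.sites),
        "site_first_fix": site_first_fix,
        "arrival_dates": arrival_dates,
        "hmm_params": p,
        "config": cfg,
    }
    return traj, truth


def _bearing(lon1, lat1, lon2, lat2):
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dl = math.radians(lon2 - lon1)
    y = math.sin(dl) * math.cos(phi2)
    x = math.cos(phi1) * math.sin(phi2) - math.sin(phi1) * math.cos(phi2) * math.cos(dl)
    return math.atan2(y, x)


def simulate_step_series(
    params: HmmParams | None = None,
    n_steps: int = 20000,
    seed: int = 0,
    stationary_hours: bool = True,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw an observation stream straight from the HMM, with true states.

    Returns ``(obs, states)`` where ``obs`` has the columns consumed by
    :mod:`phenotrack.movement_hmm` and ``states`` is 1-based.
    """
    p = params or _default_hmm_params()
    rng = np.random.default_rng(seed)
    S = p.n_states
    hours = (
        np.arange(n_steps) % 24.0
        if not stationary_hours
        else np.zeros(n_steps)
    )
    from .movement_hmm import _transition_stack

    G = _transition_stack(p.beta, hours)
    states = np.empty(n_steps, dtype=int)
    states[0] = rng.choice(S, p=p.delta)
    for t in range(1, n_steps):
        states[t] = rng.choice(S, p=G[t, states[t - 1]])

    x = np.empty(n_steps)
    a = np.empty(n_steps)
    for t in range(n_steps):
        s = states[t]
        if rng.random() < p.step_zero_mass[s]:
            x[t] = 0.0
            a[t] = np.nan
        else:
            shape = (p.step_mean[s] / p.step_sd[s]) ** 2
            scale = p.step_sd[s] ** 2 / p.step_mean[s]
            x[t] = rng.gamma(shape, scale)
            # truncated Weibull on (0, pi], symmetric sign
            while True:
                ang = rng.weibull(p.angle_shape[s]) * p.angle_scale[s]
                if 0.0 < ang <= math.pi:
                    break
            a[t] = ang if rng.random() < 0.5 else -ang
    a[0] = np.nan  # no heading change defined at the first interval
    obs = pd.DataFrame({"sqrt_step": x, "turn_angle": a, "solar_hour": hours})
    return obs, states + 1


# ---------------------------------------------------------------------------
# temperature
# ---------------------------------------------------------------------------

@dataclass
class TemperatureConfig:
    """Grid of seasonal temperature series with known 5-degree crossings.

    The noise-free daily mean at a cell is a linear ramp through the
    reference temperature: ``t_ref + slope * (doy - crossing + 0.5)``,
    so the first day above ``t_ref`` is exactly ``crossing``.
    """

    lons: tuple = tuple(np.arange(10.0, 20.0, 1.0))
    lats: tuple = tuple(np.arange(50.0, 60.0, 1.0))
    years: tuple = (2018, 2019, 2020)
    crossing_base: float = 100.0
    crossing_per_cell_north: float = 2.0  # days later per latitude step
    year_offset: dict = field(default_factory=dict)  # year -> days
    year_cell_jitter_sd: float = 0.0  # per cell-year crossing-day jitter
    slope: float = 0.15  # deg C per day
    t_ref: float = 5.0
    diurnal_amplitude: float = 3.0
    noise_sd: float = 0.0


def simulate_temperature(
    config: TemperatureConfig | None = None, seed: int = 0
) -> tuple[xr.DataArray, dict]:
    """Hourly 2-m temperature grid plus per-cell-year crossing truth."""
    cfg = config or TemperatureConfig()
    rng = np.random.default_rng(seed)
    lons = np.asarray(cfg.lons, dtype=float)
    lats = np.asarray(cfg.lats, dtype=float)

    times = []
    blocks = []
    truth_crossing: dict[tuple[int, int, int], float] = {}
    for year in cfg.years:
        t0 = pd.Timestamp(f"{year}-01-01")
        t1 = pd.Timestamp(f"{year}-12-31T23:00:00")
        hours = pd.date_range(t0, t1, freq="h")
        doy = hours.dayofyear.to_numpy()
        hod = hours.hour.to_numpy()
        n_days = int(doy.max())
        arr = np.empty((len(hours), len(lats), len(lons)))
        diurnal = cfg.diurnal_amplitude * np.sin(2.0 * np.pi * hod / 24.0)
        for li in range(len(lats)):
            for lo in range(len(lons)):
                crossing = (
                    cfg.crossing_base
                    + cfg.crossing_per_cell_north * li
                    + cfg.year_offset.get(year, 0.0)
                )
                if cfg.year_cell_jitter_sd > 0:
                    crossing += rng.normal(0.0, cfg.year_cell_jitter_sd)
                daily = cfg.t_ref + cfg.slope * (doy - crossing + 0.5)
                noise = (
                    rng.normal(0.0, cfg.noise_sd, len(hours))
                    if cfg.noise_sd > 0
                    else 0.0
                )
                arr[:, li, lo] = daily + diurnal + noise
                # first integer day with daily mean above t_ref
                truth_crossing[(year, li, lo)] = float(
                    math.floor(crossing - 0.5) + 1
                )
        times.append(hours)
        blocks.append(arr)

    time = times[0].append(times[1:]) if len(times) > 1 else times[0]
    data = np.concatenate(blocks, axis=0)
    da = xr.DataArray(
        data,
        coords={"time": time, "latitude": lats, "longitude": lons},
        dims=("time", "latitude", "longitude"),
        name="t2m",
        attrs={"units": "degC"},
    )
    truth = {"crossing_day": truth_crossing, "config": cfg}
    return da, truth


# ---------------------------------------------------------------------------
# ring recoveries
# ---------------------------------------------------------------------------

@dataclass
class RingConfig:
    schemes: tuple = ("Arnhem", "London", "Moscow")
    bands: tuple = tuple(range(0, 80, 10))
    n_per_band: int = 20
    mean_base: float = 85.0  # DOY at band 0
    mean_slope: float = 8.0  # days later per band eastward
    sd_days: float = 6.0
    year: int = 2015
    lat: float = 55.0


def simulate_ring_recoveries(
    config: RingConfig | None = None, seed: int = 0
) -> tuple[pd.DataFrame, dict]:
    """Ring-recovery table with band-specific mean passage dates."""
    cfg = config or RingConfig()
    rng = np.random.default_rng(seed)
    rows = []
    means: dict[tuple[str, int], float] = {}
    k = 0
    for scheme in cfg.schemes:
        for band in cfg.bands:
            mean_doy = cfg.mean_base + cfg.mean_slope * (band / 10.0)
            means[(scheme, band)] = mean_doy
            for _ in range(cfg.n_per_band):
                doy = int(np.clip(round(rng.normal(mean_doy, cfg.sd_days)), 32, 181))
                when = pd.Timestamp(f"{cfg.year}-01-01") + pd.Timedelta(days=doy - 1)
                rows.append(
                    {
                        "scheme": scheme,
                        "ring_id": f"{scheme[:2].upper()}{k:06d}",
                        "event_type": "recovery",
                        "date": when.date().isoformat(),
                        "lon": float(rng.uniform(band, band + 10.0)),
                        "lat": cfg.lat,
                    }
                )
                k += 1
    df = pd.DataFrame(rows)
    return df, {"band_means": means, "config": cfg}


# ---------------------------------------------------------------------------
# arrival datasets
# ---------------------------------------------------------------------------

@dataclass
class ArrivalSimConfig:
    """Mixed-model generative settings (covariates on the z-scale)."""

    n_individuals: int = 30
    two_season_prob: float = 0.15
    events_per_group: int = 7
    beta: dict = field(
        default_factory=lambda: {
            "intercept[LTU]": 0.1,
            "intercept[NLD]": 0.5,
            "tgs_deviation": -0.3,
            "max_longitude": -0.5,
            "max_longitude:distance_traveled[LTU]": -0.17,
            "max_longitude:distance_traveled[NLD]": -0.26,
        }
    )
    s2_individual: float = 0.1
    s2_individual_year: float = 0.1
    s2_ou: float = 0.2
    rho: float = 5.0
    s2_resid: float = 0.2
    years: tuple = (2018, 2019, 2020)


def simulate_arrival_dataset(
    config: ArrivalSimConfig | None = None, seed: int = 0
) -> tuple[pd.DataFrame, dict]:
    """Arrival records with known fixed effects and OU residuals.

    Covariates are generated directly on the scaled (z) scale; the
    response follows the full-variant design of
    :func:`phenotrack.arrival_model.build_design`.
    """
    from .arrival_model import build_design, ou_correlation

    cfg = config or ArrivalSimConfig()
    rng = np.random.default_rng(seed)

    rows = []
    for i in range(cfg.n_individuals):
        ind = f"bird-{i:03d}"
        site = "NLD" if rng.random() < 0.6 else "LTU"
        n_years = 2 if rng.random() < cfg.two_season_prob else 1
        years = rng.choice(cfg.years, size=n_years, replace=False)
        for year in np.sort(years):
            n_ev = max(2, int(rng.poisson(cfg.events_per_group)))
            mlon = float(rng.normal(0.0, 1.0))
            dev = float(rng.normal(0.0, 1.0))
            day = float(rng.uniform(60, 110))
            dist = float(rng.normal(-1.0, 0.3))
            for _ in range(n_ev):
                rows.append(
                    {
                        "individual_id": ind,
                        "year": int(year),
                        "capture_site": site,
                        "arrival_doy": round(day),
                        "tgs_deviation_scaled": dev,
                        "max_longitude_scaled": mlon,
                        "distance_traveled_scaled": dist,
                    }
                )
                day += float(rng.uniform(2.0, 10.0))
                dist += float(rng.uniform(0.1, 0.6))
    df = pd.DataFrame(rows)

    X, names = build_design(df, "full")
    beta = np.array([cfg.beta[n] for n in names])
    mu = X @ beta

    y = mu.copy()
    for ind, grp in df.groupby("individual_id"):
        b_ind = rng.normal(0.0, math.sqrt(cfg.s2_individual))
        y[grp.index] += b_ind
        for year, sub in grp.groupby("year"):
            b_iy = rng.normal(0.0, math.sqrt(cfg.s2_individual_year))
            t = sub["arrival_doy"].to_numpy(dtype=float)
            cov = cfg.s2_ou * ou_correlation(t, cfg.rho) + cfg.s2_resid * np.eye(len(t))
            resid = rng.multivariate_normal(np.zeros(len(t)), cov, method="svd")
            y[sub.index] += b_iy + resid
    df["delta_arrival_d_scaled"] = y

    truth = {
        "beta": dict(zip(names, beta)),
        "s2_individual": cfg.s2_individual,
        "s2_individual_year": cfg.s2_individual_year,
        "s2_ou": cfg.s2_ou,
        "rho": cfg.rho,
        "s2_resid": cfg.s2_resid,
        "config": cfg,
    }
    return df, truth
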