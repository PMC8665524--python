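"""Geodesic distances, a two-point equidistant projection, and solar time.

Coordinates are always ``(lon, lat)`` in decimal degrees on WGS84.
Distances are kilometres.  The default reference surface is the WGS84
ellipsoid (Vincenty's inverse formulae); a spherical surface with the
IUGG mean radius is available via ``model="sphere"`` where closed forms
are wanted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

# WGS84 defining parameters
_WGS84_A = 6378137.0  # semi-major axis, m
_WGS84_F = 1.0 / 298.257223563
_WGS84_B = _WGS84_A * (1.0 - _WGS84_F)

#: IUGG mean Earth radius, km (used by the spherical fallback).
EARTH_RADIUS_KM = 6371.0088

#: Default projection anchors: the two capture sites
#: (polder near Krommeniedijk, NL and the Nemunas delta, LT).
DEFAULT_ANCHORS = ((4.77, 52.49), (21.3, 55.3))


@dataclass(frozen=True)
class GeoPoint:
    """A WGS84 longitude/latitude pair in decimal degrees."""

    lon: float
    lat: float

    def __post_init__(self) -> None:
        if not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"longitude {self.lon} outside [-180, 180]")
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")


@dataclass(frozen=True)
class ProjectedPoint:
    """Planar point of the two-point equidistant projection, km."""

    x: float  # along the corridor axis ("longitude")
    y: float  # across the corridor axis ("latitude")


def _as_lonlat(p) -> tuple[float, float]:
    if isinstance(p, GeoPoint):
        return p.lon, p.lat
    lon, lat = float(p[0]), float(p[1])
    GeoPoint(lon, lat)  # validate
    return lon, lat


def _vincenty_inverse(lon1, lat1, lon2, lat2, tol=1e-12, maxiter=200):
    """Distance (m) and forward azimuth (rad) on the WGS84 ellipsoid.

    Returns ``(s, alpha1)``.  Raises ``RuntimeError`` when the
    iteration fails to converge (nearly antipodal points).
    """
    if lon1 == lon2 and lat1 == lat2:
        return 0.0, 0.0
    a, b, f = _WGS84_A, _WGS84_B, _WGS84_F
    L = math.radians(lon2 - lon1)
    U1 = math.atan((1 - f) * math.tan(math.radians(lat1)))
    U2 = math.atan((1 - f) * math.tan(math.radians(lat2)))
    sinU1, cosU1 = math.sin(U1), math.cos(U1)
    sinU2, cosU2 = math.sin(U2), math.cos(U2)

    lam = L
    for _ in range(maxiter):
        sin_lam, cos_lam = math.sin(lam), math.cos(lam)
        sin_sigma = math.hypot(
            cosU2 * sin_lam, cosU1 * sinU2 - sinU1 * cosU2 * cos_lam
        )
        if sin_sigma == 0.0:
            return 0.0, 0.0  # coincident
        cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
        sigma = math.atan2(sin_sigma, cos_sigma)
        sin_alpha = cosU1 * cosU2 * sin_lam / sin_sigma
        cos2_alpha = 1.0 - sin_alpha * sin_alpha
        if cos2_alpha == 0.0:
            cos_2sigma_m = 0.0  # equatorial line
        else:
            cos_2sigma_m = cos_sigma - 2.0 * sinU1 * sinU2 / cos2_alpha
        C = f / 16.0 * cos2_alpha * (4.0 + f * (4.0 - 3.0 * cos2_alpha))
        lam_prev = lam
        lam = L + (1.0 - C) * f * sin_alpha * (
            sigma
            + C
            * sin_sigma
            * (
                cos_2sigma_m
                + C * cos_sigma * (-1.0 + 2.0 * cos_2sigma_m * cos_2sigma_m)
            )
        )
        if abs(lam - lam_prev) < tol:
            break
    else:
        raise RuntimeError("Vincenty inverse did not converge")

    u2 = cos2_alpha * (a * a - b * b) / (b * b)
    A = 1.0 + u2 / 16384.0 * (4096.0 + u2 * (-768.0 + u2 * (320.0 - 175.0 * u2)))
    B = u2 / 1024.0 * (256.0 + u2 * (-128.0 + u2 * (74.0 - 47.0 * u2)))
    delta_sigma = (
        B
        * sin_sigma
        * (
            cos_2sigma_m
            + B
            / 4.0
            * (
                cos_sigma * (-1.0 + 2.0 * cos_2sigma_m**2)
                - B
                / 6.0
                * cos_2sigma_m
                * (-3.0 + 4.0 * sin_sigma**2)
                * (-3.0 + 4.0 * cos_2sigma_m**2)
            )
        )
    )
    s = b * A * (sigma - delta_sigma)
    alpha1 = math.atan2(
        cosU2 * math.sin(lam), cosU1 * sinU2 - sinU1 * cosU2 * math.cos(lam)
    )
    return s, alpha1


def _haversine_km(lon1, lat1, lon2, lat2, radius=EARTH_RADIUS_KM):
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlmb = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(
        dlmb / 2.0
    ) ** 2
    return 2.0 * radius * math.asin(min(1.0, math.sqrt(h)))


def geodesic_km(a, b, model: str = "wgs84") -> float:
    """Geodesic distance between two ``(lon, lat)`` points, km.

    Parameters
    ----------
    a, b : GeoPoint or (lon, lat)
    model : {"wgs84", "sphere"}
        Reference surface.  ``"wgs84"`` uses Vincenty's inverse formula;
        ``"sphere"`` a great circle of radius ``EARTH_RADIUS_KM``.
        Nearly antipodal points on the ellipsoid fall back to the
        spherical value.
    """
    lon1, lat1 = _as_lonlat(a)
    lon2, lat2 = _as_lonlat(b)
    if model == "sphere":
        return _haversine_km(lon1, lat1, lon2, lat2)
    if model != "wgs84":
        raise ValueError(f"unknown model {model!r}")
    try:
        s, _ = _vincenty_inverse(lon1, lat1, lon2, lat2)
    except RuntimeError:
        return _haversine_km(lon1, lat1, lon2, lat2)
    return s / 1000.0


def initial_bearing_rad(a, b, model: str = "wgs84") -> float:
    """Forward azimuth of the geodesic from ``a`` to ``b``, radians.

    Measured clockwise from north, in ``(-pi, pi]``.  Undefined (returns
    0.0) for coincident points.
    """
    lon1, lat1 = _as_lonlat(a)
    lon2, lat2 = _as_lonlat(b)
    if model == "sphere":
        phi1, phi2 = math.radians(lat1), math.radians(lat2)
        dlmb = math.radians(lon2 - lon1)
        y = math.sin(dlmb) * math.cos(phi2)
        x = math.cos(phi1) * math.sin(phi2) - math.sin(phi1) * math.cos(
            phi2
        ) * math.cos(dlmb)
        return math.atan2(y, x)
    try:
        _, alpha1 = _vincenty_inverse(lon1, lat1, lon2, lat2)
    except RuntimeError:
        return initial_bearing_rad(a, b, model="sphere")
    return alpha1


def _unit_vector(lon, lat):
    phi, lmb = math.radians(lat), math.radians(lon)
    return np.array(
        [math.cos(phi) * math.cos(lmb), math.cos(phi) * math.sin(lmb), math.sin(phi)]
    )


def project_two_point(
    points: Iterable,
    anchors: Sequence = DEFAULT_ANCHORS,
    model: str = "wgs84",
) -> list[ProjectedPoint]:
    """Two-point equidistant projection of ``points``.

    The defining property: planar distances from every projected point
    to the two projected anchors equal the geodesic distances to the
    geographic anchors.  Anchor A maps to ``(0, 0)`` and anchor B to
    ``(d_AB, 0)``, so ``x`` runs along the corridor axis.  Points on
    the northern side of the A-to-B great circle get positive ``y``.
    """
    (lon_a, lat_a), (lon_b, lat_b) = (_as_lonlat(p) for p in anchors)
    d_ab = geodesic_km((lon_a, lat_a), (lon_b, lat_b), model=model)
    if d_ab == 0.0:
        raise ValueError("projection anchors coincide")
    if d_ab > 0.999 * math.pi * EARTH_RADIUS_KM:
        raise ValueError("projection anchors are (nearly) antipodal")

    va, vb = _unit_vector(lon_a, lat_a), _unit_vector(lon_b, lat_b)
    normal = np.cross(va, vb)  # points to the northern side for W-E anchors

    out = []
    for p in points:
        lon, lat = _as_lonlat(p)
        d1 = geodesic_km((lon, lat), (lon_a, lat_a), model=model)
        d2 = geodesic_km((lon, lat), (lon_b, lat_b), model=model)
        x = (d1 * d1 - d2 * d2 + d_ab * d_ab) / (2.0 * d_ab)
        y2 = d1 * d1 - x * x
        y = math.sqrt(y2) if y2 > 0.0 else 0.0
        side = float(np.dot(normal, _unit_vector(lon, lat)))
        if side < 0.0:
            y = -y
        out.append(ProjectedPoint(x, y))
    return out


def solar_hour(timestamp, lon: float, apparent: bool = False) -> float:
    """Fractional hours since solar midnight at longitude ``lon``.

    Mean solar time by default: ``(UTC hours + lon / 15) mod 24``.  With
    ``apparent=True`` the equation of time (Spencer's Fourier fit) is
    added.
    """
    ts = pd.Timestamp(timestamp)
    if ts.tzinfo is not None:
        ts = ts.tz_convert("UTC").tz_localize(None)
    utc_hours = ts.hour + ts.minute / 60.0 + ts.second / 3600.0 + ts.microsecond / 3.6e9
    h = utc_hours + lon / 15.0
    if apparent:
        doy = ts.dayofyear
        g = 2.0 * math.pi * (doy - 1) / 365.0
        eot_min = 229.18 * (
            0.000075
            + 0.001868 * math.cos(g)
            - 0.032077 * math.sin(g)
            - 0.014615 * math.cos(2 * g)
            - 0.040849 * math.sin(2 * g)
        )
        h += eot_min / 60.0
    return h % 24.0
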