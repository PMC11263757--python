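"""WGS84 <-> UTM coordinate transforms.

Metric buffering requires fixes in a projected, meter-unit CRS, while GPX
waypoints and web maps require WGS84 geographic coordinates, so the package
needs both directions of the transverse Mercator projection.  This module
implements the Karney-Krüger series (fourth order in the third flattening
n ~ 1.68e-3) for the UTM zones of WGS84, EPSG 32601-32660 (north) and
32701-32760 (south).  Truncation error at fourth order is below 0.1 mm
anywhere inside a UTM zone, far inside the 1e-6 degree (~0.1 m) round-trip
tolerance the exporters rely on; the test suite checks the northing of the
central meridian against a numerically integrated meridian arc.
"""

from __future__ import annotations

import math
from typing import Iterable, Tuple

import numpy as np

__all__ = [
    "is_utm_epsg",
    "utm_zone",
    "lonlat_to_projected",
    "projected_to_lonlat",
]

# WGS84 ellipsoid
_A = 6378137.0
_F = 1.0 / 298.257223563
_E = math.sqrt(_F * (2.0 - _F))
_N = _F / (2.0 - _F)  # third flattening

_K0 = 0.9996
_FALSE_EASTING = 500000.0
_FALSE_NORTHING_SOUTH = 10000000.0

# rectifying radius
_AHAT = _A / (1.0 + _N) * (1.0 + _N**2 / 4.0 + _N**4 / 64.0 + _N**6 / 256.0)

# Krüger series coefficients, fourth order in n
_ALPHA = (
    _N / 2.0 - 2.0 * _N**2 / 3.0 + 5.0 * _N**3 / 16.0 + 41.0 * _N**4 / 180.0,
    13.0 * _N**2 / 48.0 - 3.0 * _N**3 / 5.0 + 557.0 * _N**4 / 1440.0,
    61.0 * _N**3 / 240.0 - 103.0 * _N**4 / 140.0,
    49561.0 * _N**4 / 161280.0,
)
_BETA = (
    _N / 2.0 - 2.0 * _N**2 / 3.0 + 37.0 * _N**3 / 96.0 - _N**4 / 360.0,
    _N**2 / 48.0 + _N**3 / 15.0 - 437.0 * _N**4 / 1440.0,
    17.0 * _N**3 / 480.0 - 37.0 * _N**4 / 840.0,
    4397.0 * _N**4 / 161280.0,
)
# conformal latitude -> geodetic latitude
_DELTA = (
    2.0 * _N - 2.0 * _N**2 / 3.0 - 2.0 * _N**3 + 116.0 * _N**4 / 45.0,
    7.0 * _N**2 / 3.0 - 8.0 * _N**3 / 5.0 - 227.0 * _N**4 / 45.0,
    56.0 * _N**3 / 15.0 - 136.0 * _N**4 / 35.0,
    4279.0 * _N**4 / 630.0,
)


def is_utm_epsg(epsg: int) -> bool:
    return 32601 <= epsg <= 32660 or 32701 <= epsg <= 32760


def utm_zone(epsg: int) -> Tuple[int, bool]:
    """Return (zone number, is_north) for a WGS84 UTM EPSG code."""
    if 32601 <= epsg <= 32660:
        return epsg - 32600, True
    if 32701 <= epsg <= 32760:
        return epsg - 32700, False
    raise ValueError(
        f"EPSG:{epsg} is not a WGS84 UTM zone (32601-32660 / 32701-32760); "
        "supply coordinates already projected in your study CRS"
    )


def _central_meridian(zone: int) -> float:
    return math.radians(-183.0 + 6.0 * zone)


def lonlat_to_projected(lon, lat, epsg: int):
    """Project WGS84 degrees to UTM easting/northing (meters) for ``epsg``.

    Accepts scalars or array-likes; returns numpy arrays (scalar in, 0-d out
    is converted to float).
    """
    zone, north = utm_zone(epsg)
    lam0 = _central_meridian(zone)
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    scalar = lon.ndim == 0 and lat.ndim == 0
    phi = np.radians(lat)
    dlam = np.radians(lon) - lam0
    # wrap to (-pi, pi]
    dlam = (dlam + math.pi) % (2.0 * math.pi) - math.pi

    sphi = np.sin(phi)
    # conformal latitude via Gauss-Schreiber
    t = np.sinh(
        np.arctanh(sphi) - _E * np.arctanh(_E * sphi)
    )
    xi_p = np.arctan2(t, np.cos(dlam))
    eta_p = np.arctanh(np.sin(dlam) / np.sqrt(1.0 + t**2))

    xi = xi_p.copy()
    eta = eta_p.copy()
    for j, a in enumerate(_ALPHA, start=1):
        xi = xi + a * np.sin(2 * j * xi_p) * np.cosh(2 * j * eta_p)
        eta = eta + a * np.cos(2 * j * xi_p) * np.sinh(2 * j * eta_p)

    easting = _FALSE_EASTING + _K0 * _AHAT * eta
    northing = _K0 * _AHAT * xi
    if not north:
        northing = northing + _FALSE_NORTHING_SOUTH
    if scalar:
        return float(easting), float(northing)
    return easting, northing


def projected_to_lonlat(easting, northing, epsg: int):
    """Inverse-project UTM meters back to WGS84 degrees (lon, lat)."""
    zone, north = utm_zone(epsg)
    lam0 = _central_meridian(zone)
    easting = np.asarray(easting, dtype=float)
    northing = np.asarray(northing, dtype=float)
    scalar = easting.ndim == 0 and northing.ndim == 0
    if not north:
        northing = northing - _FALSE_NORTHING_SOUTH

    xi = northing / (_K0 * _AHAT)
    eta = (easting - _FALSE_EASTING) / (_K0 * _AHAT)

    xi_p = xi.copy()
    eta_p = eta.copy()
    for j, b in enumerate(_BETA, start=1):
        xi_p = xi_p - b * np.sin(2 * j * xi) * np.cosh(2 * j * eta)
        eta_p = eta_p - b * np.cos(2 * j * xi) * np.sinh(2 * j * eta)

    # Gauss-Schreiber back to conformal latitude chi, then geodetic phi
    chi = np.arcsin(np.clip(np.sin(xi_p) / np.cosh(eta_p), -1.0, 1.0))
    phi = chi.copy()
    for j, d in enumerate(_DELTA, start=1):
        phi = phi + d * np.sin(2 * j * chi)
    dlam = np.arctan2(np.sinh(eta_p), np.cos(xi_p))

    lon = np.degrees(lam0 + dlam)
    lon = (lon + 180.0) % 360.0 - 180.0
    lat = np.degrees(phi)
    if scalar:
        return float(lon), float(lat)
    return lon, lat


def derive_lonlat(fixes: Iterable, epsg: int) -> None:
    """Fill missing ``lon``/``lat`` on fixes in place from projected x/y.

    No-op for fixes that already carry geographic coordinates.  Raises
    ``ValueError`` when ``epsg`` is not a supported UTM zone.
    """
    todo = [f for f in fixes if f.lon is None or f.lat is None]
    if not todo:
        return
    xs = np.array([f.x for f in todo])
    ys = np.array([f.y for f in todo])
    lon, lat = projected_to_lonlat(xs, ys, epsg)
    for f, lo, la in zip(todo, lon, lat):
        f.lon = float(lo)
        f.lat = float(la)
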