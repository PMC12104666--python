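"""Spherical geodesy primitives.

Distances are great-circle (haversine) kilometres on a sphere with the
authalic Earth radius, matching the convention used for natal dispersal
distances between nest coordinates recorded in WGS84 decimal degrees.
A local Lambert azimuthal equal-area (LAEA) projection supports planar
area computations (Thiessen polygons) with negligible area distortion
over a few hundred kilometres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Authalic (equal-area) Earth radius, km.
EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class GeoPoint:
    """A WGS84 point in decimal degrees."""

    lon: float
    lat: float

    def __post_init__(self) -> None:
        if not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"longitude out of range: {self.lon}")
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"latitude out of range: {self.lat}")


def great_circle_distance(a, b) -> float:
    """Great-circle distance in km between two lon/lat points (haversine).

    Accepts :class:`GeoPoint` or ``(lon, lat)`` pairs. Symmetric,
    non-negative and zero iff the points coincide.
    """
    lon1, lat1 = _unpack(a)
    lon2, lat2 = _unpack(b)
    return float(haversine_km(lon1, lat1, lon2, lat2))


def haversine_km(lon1, lat1, lon2, lat2):
    """Vectorised haversine distance in km (inputs in decimal degrees)."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def initial_bearing(a, b) -> float:
    """Initial (forward) bearing from ``a`` to ``b`` in compass degrees.

    0 = geographic north, 90 = east; result in [0, 360). Raises
    ``ValueError`` for coincident points, whose direction is undefined.
    """
    lon1, lat1 = _unpack(a)
    lon2, lat2 = _unpack(b)
    if lon1 == lon2 and lat1 == lat2:
        raise ValueError("bearing undefined for coincident points")
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dlon = np.radians(lon2 - lon1)
    y = np.sin(dlon) * np.cos(phi2)
    x = np.cos(phi1) * np.sin(phi2) - np.sin(phi1) * np.cos(phi2) * np.cos(dlon)
    theta = np.degrees(np.arctan2(y, x))
    return float(theta % 360.0)


class LocalEqualAreaProjection:
    """Spherical Lambert azimuthal equal-area projection centred on a point.

    Maps lon/lat (degrees) to planar x/y kilometres. Equal-area by
    construction, so polygon areas computed in the projected frame are
    true sphere areas; distortion of shape grows with distance from the
    centre but is irrelevant for area at a ~500 km study-region scale.
    """

    #: Angular distance from the centre (degrees) beyond which points are refused.
    VALIDITY_DEG = 30.0

    def __init__(self, lon0: float, lat0: float):
        self.lon0 = float(lon0)
        self.lat0 = float(lat0)
        self._phi0 = np.radians(lat0)
        self._lam0 = np.radians(lon0)

    @classmethod
    def for_points(cls, lons, lats) -> "LocalEqualAreaProjection":
        """Projection centred on the centroid of a point set."""
        return cls(float(np.mean(lons)), float(np.mean(lats)))

    def forward(self, lon, lat):
        """lon/lat degrees -> (x, y) km. Vectorised."""
        lam = np.radians(np.asarray(lon, dtype=float))
        phi = np.radians(np.asarray(lat, dtype=float))
        cosc = np.sin(self._phi0) * np.sin(phi) + np.cos(self._phi0) * np.cos(phi) * np.cos(
            lam - self._lam0
        )
        if np.any(np.degrees(np.arccos(np.clip(cosc, -1, 1))) > self.VALIDITY_DEG):
            raise ValueError(
                "point beyond projection validity zone "
                f"({self.VALIDITY_DEG} deg from centre)"
            )
        # k' = sqrt(2 / (1 + cos c)); at the antipode the projection is singular
        k = np.sqrt(2.0 / (1.0 + cosc))
        x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(lam - self._lam0)
        y = EARTH_RADIUS_KM * k * (
            np.cos(self._phi0) * np.sin(phi)
            - np.sin(self._phi0) * np.cos(phi) * np.cos(lam - self._lam0)
        )
        return x, y

    def inverse(self, x, y):
        """(x, y) km -> lon/lat degrees. Vectorised."""
        x = np.asarray(x, dtype=float) / EARTH_RADIUS_KM
        y = np.asarray(y, dtype=float) / EARTH_RADIUS_KM
        rho = np.hypot(x, y)
        c = 2.0 * np.arcsin(np.clip(rho / 2.0, 0.0, 1.0))
        with np.errstate(invalid="ignore", divide="ignore"):
            phi = np.where(
                rho == 0,
                self._phi0,
                np.arcsin(
                    np.clip(
                        np.cos(c) * np.sin(self._phi0)
                        + np.where(rho == 0, 0.0, y * np.sin(c) / np.where(rho == 0, 1.0, rho))
                        * np.cos(self._phi0),
                        -1.0,
                        1.0,
                    )
                ),
            )
            lam = self._lam0 + np.arctan2(
                x * np.sin(c),
                rho * np.cos(self._phi0) * np.cos(c) - y * np.sin(self._phi0) * np.sin(c),
            )
        return np.degrees(lam), np.degrees(phi)


def _unpack(p):
    if isinstance(p, GeoPoint):
        return p.lon, p.lat
    lon, lat = p
    return float(lon), float(lat)
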