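"""Map projection and geodesic helpers.

All metric geometry in this package (buffers, areas, centroids, zonal grids)
happens in a single equal-area planar coordinate system.  We use a spherical
Albers equal-area conic projection on the authalic sphere: areas are preserved
exactly on the sphere, which is what matters for buffer-dissolve delineation
and km^2 summaries.  The defaults mimic the continental-US Albers setup
(standard parallels 29.5/45.5, central meridian -96) so coordinates land in a
familiar range, but any parallels bracketing the study area work.

Short-range point-to-point distances (duplicate detection at the 10 m scale)
use the haversine great-circle formula instead of projecting first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: authalic Earth radius, meters
EARTH_RADIUS_M = 6_371_007.2


@dataclass(frozen=True)
class AlbersEqualArea:
    """Spherical Albers equal-area conic projection (forward and inverse).

    Parameters are in decimal degrees.  ``lat1``/``lat2`` are the standard
    parallels, ``lon0``/``lat0`` the projection origin.  Forward maps
    (lon, lat) in WGS84 degrees to (x, y) in meters.
    """

    lat1: float = 29.5
    lat2: float = 45.5
    lon0: float = -96.0
    lat0: float = 23.0

    @property
    def _n(self) -> float:
        p1, p2 = np.radians(self.lat1), np.radians(self.lat2)
        return (np.sin(p1) + np.sin(p2)) / 2.0

    @property
    def _c(self) -> float:
        p1 = np.radians(self.lat1)
        return np.cos(p1) ** 2 + 2.0 * self._n * np.sin(p1)

    def _rho(self, lat_rad):
        n = self._n
        return EARTH_RADIUS_M * np.sqrt(np.maximum(self._c - 2.0 * n * np.sin(lat_rad), 0.0)) / n

    def forward(self, lon, lat):
        """Project (lon, lat) degrees -> (x, y) meters.  Accepts scalars or arrays."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        n = self._n
        theta = n * (np.radians(lon) - np.radians(self.lon0))
        rho = self._rho(np.radians(lat))
        rho0 = self._rho(np.radians(self.lat0))
        x = rho * np.sin(theta)
        y = rho0 - rho * np.cos(theta)
        return x, y

    def inverse(self, x, y):
        """Unproject (x, y) meters -> (lon, lat) degrees."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        n = self._n
        rho0 = self._rho(np.radians(self.lat0))
        rho = np.hypot(x, rho0 - y)
        theta = np.arctan2(x, rho0 - y)
        sin_lat = (self._c - (rho * n / EARTH_RADIUS_M) ** 2) / (2.0 * n)
        lat = np.degrees(np.arcsin(np.clip(sin_lat, -1.0, 1.0)))
        lon = self.lon0 + np.degrees(theta / n)
        return lon, lat


def haversine_m(lon1, lat1, lon2, lat2):
    """Great-circle distance in meters between points in decimal degrees."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


DEFAULT_PROJECTION = AlbersEqualArea()
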