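"""Planar map projection for survey geometry.

Survey files carry WGS84 decimal degrees; all internal geometry (transect
lengths, segment midpoints, prediction grids) is done in projected metres.
The projection is a Lambert Conformal Conic with two standard parallels on
the WGS84 ellipsoid — the conformal family conventionally used for
mid-latitude east-west study regions such as the Mediterranean.  Parameters
are configurable; :func:`Projection.for_bounds` derives a sensible
parameterization from a study bounding box.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["Projection", "ProjectionError"]

# WGS84 ellipsoid
_A = 6378137.0
_F = 1.0 / 298.257223563
_E2 = _F * (2.0 - _F)
_E = math.sqrt(_E2)


class ProjectionError(ValueError):
    """Raised for malformed projection specs or out-of-domain coordinates."""


def _m(phi: np.ndarray) -> np.ndarray:
    return np.cos(phi) / np.sqrt(1.0 - _E2 * np.sin(phi) ** 2)


def _t(phi: np.ndarray) -> np.ndarray:
    sphi = np.sin(phi)
    return np.tan(np.pi / 4.0 - phi / 2.0) / (
        (1.0 - _E * sphi) / (1.0 + _E * sphi)
    ) ** (_E / 2.0)


@dataclass(frozen=True)
class Projection:
    """Lambert Conformal Conic (2 standard parallels) on WGS84.

    Angles in the spec are decimal degrees; planar output is metres.
    """

    lat1: float
    lat2: float
    lat0: float
    lon0: float
    x0: float = 0.0
    y0: float = 0.0

    def __post_init__(self) -> None:
        for name in ("lat1", "lat2", "lat0"):
            v = getattr(self, name)
            if not -89.9 < v < 89.9:
                raise ProjectionError(f"{name}={v} outside (-89.9, 89.9)")
        if not -180.0 <= self.lon0 <= 180.0:
            raise ProjectionError(f"lon0={self.lon0} outside [-180, 180]")
        phi1, phi2 = math.radians(self.lat1), math.radians(self.lat2)
        m1, m2 = _m(np.array(phi1)), _m(np.array(phi2))
        t1, t2 = _t(np.array(phi1)), _t(np.array(phi2))
        if abs(phi1 - phi2) > 1e-12:
            n = (math.log(m1) - math.log(m2)) / (math.log(t1) - math.log(t2))
        else:
            n = math.sin(phi1)
        if abs(n) < 1e-12:
            raise ProjectionError("standard parallels symmetric about equator")
        F = m1 / (n * t1**n)
        rho0 = _A * F * _t(np.array(math.radians(self.lat0))) ** n
        object.__setattr__(self, "_n", float(n))
        object.__setattr__(self, "_F", float(F))
        object.__setattr__(self, "_rho0", float(rho0))

    # -- spec / config plumbing -------------------------------------------

    @classmethod
    def from_spec(cls, spec: dict | "Projection") -> "Projection":
        """Build from a config mapping like ``{"kind": "lcc", "lat1": ...}``."""
        if isinstance(spec, Projection):
            return spec
        if not isinstance(spec, dict):
            raise ProjectionError(f"projection spec must be a mapping, got {type(spec).__name__}")
        kind = spec.get("kind", "lcc")
        if kind != "lcc":
            raise ProjectionError(f"unsupported projection kind {kind!r} (supported: 'lcc')")
        try:
            return cls(
                lat1=float(spec["lat1"]),
                lat2=float(spec["lat2"]),
                lat0=float(spec["lat0"]),
                lon0=float(spec["lon0"]),
                x0=float(spec.get("x0", 0.0)),
                y0=float(spec.get("y0", 0.0)),
            )
        except KeyError as exc:
            raise ProjectionError(f"projection spec missing key {exc}") from exc

    @classmethod
    def for_bounds(
        cls, lat_min: float, lat_max: float, lon_min: float, lon_max: float
    ) -> "Projection":
        """Parameterize for a study bounding box (1/6-rule standard parallels)."""
        span = lat_max - lat_min
        if span <= 0:
            raise ProjectionError("lat_max must exceed lat_min")
        return cls(
            lat1=lat_min + span / 6.0,
            lat2=lat_max - span / 6.0,
            lat0=(lat_min + lat_max) / 2.0,
            lon0=(lon_min + lon_max) / 2.0,
        )

    # -- transforms -------------------------------------------------------

    def forward(self, lon, lat):
        """(lon, lat) degrees -> (x, y) metres.  Vectorized."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        if np.any(np.abs(lat) > 90.0) or np.any(np.abs(lon) > 180.0):
            raise ProjectionError("coordinates outside geographic domain")
        if np.any(np.abs(lat) > 89.9):
            raise ProjectionError("latitude too close to a pole for LCC")
        phi = np.radians(lat)
        n, F, rho0 = self._n, self._F, self._rho0
        rho = _A * F * _t(phi) ** n
        dlam = np.radians(((lon - self.lon0 + 180.0) % 360.0) - 180.0)
        theta = n * dlam
        x = self.x0 + rho * np.sin(theta)
        y = self.y0 + rho0 - rho * np.cos(theta)
        return x, y

    def inverse(self, x, y):
        """(x, y) metres -> (lon, lat) degrees.  Vectorized."""
        x = np.asarray(x, dtype=float) - self.x0
        y = np.asarray(y, dtype=float)
        n, F, rho0 = self._n, self._F, self._rho0
        yp = rho0 - (y - self.y0)
        rho = np.sign(n) * np.hypot(x, yp)
        theta = np.arctan2(np.sign(n) * x, np.sign(n) * yp)
        t = (rho / (_A * F)) ** (1.0 / n)
        # fixed-point iteration for the conformal latitude inversion
        phi = np.pi / 2.0 - 2.0 * np.arctan(t)
        for _ in range(15):
            sphi = np.sin(phi)
            phi = np.pi / 2.0 - 2.0 * np.arctan(
                t * ((1.0 - _E * sphi) / (1.0 + _E * sphi)) ** (_E / 2.0)
            )
        lon = self.lon0 + np.degrees(theta / n)
        lat = np.degrees(phi)
        return lon, lat
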