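"""Equal-area polar grid used by every spatial stage.

All densities, overlap indices and kernel estimates live on a regular grid in
a South-Pole-centred Lambert azimuthal equal-area (LAEA) projection on a
sphere of radius 6371 km.  Because LAEA preserves area, every cell of the
regular projected grid covers the same area on the sphere (cell_km**2), which
makes utilization-distribution mass sums exact rather than approximate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_KM = 6371.0


def project(lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """South-polar Lambert azimuthal equal-area forward projection.

    Parameters
    ----------
    lon, lat : array-like, degrees.  Latitudes must lie in [-90, 90].

    Returns
    -------
    x, y : km in the projected plane; the South Pole maps to the origin.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude outside [-90, 90]")
    # colatitude from the South Pole
    c = np.radians(lat + 90.0)
    rho = 2.0 * EARTH_RADIUS_KM * np.sin(c / 2.0)
    lam = np.radians(lon)
    return rho * np.sin(lam), rho * np.cos(lam)


def unproject(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`project`; returns (lon, lat) in degrees, lon in (-180, 180]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rho = np.hypot(x, y)
    arg = np.clip(rho / (2.0 * EARTH_RADIUS_KM), -1.0, 1.0)
    lat = np.degrees(2.0 * np.arcsin(arg)) - 90.0
    lon = np.degrees(np.arctan2(x, y))
    lon = np.where(lon <= -180.0, lon + 360.0, lon)
    return lon, lat


def normalize_lon(lon):
    """Map longitudes to (-180, 180]."""
    lon = np.asarray(lon, dtype=float)
    out = -((-lon + 180.0) % 360.0 - 180.0)
    return np.where(out == -180.0, 180.0, out)


@dataclass(frozen=True)
class SpatialGrid:
    """Regular square grid in the south-polar LAEA plane.

    The grid spans [-half_extent_km, half_extent_km) in both x and y, with
    square cells of side ``cell_km``.  ``n`` cells per axis; cell (iy, ix) has
    its centre at ``-half_extent_km + (i + 0.5) * cell_km``.
    """

    cell_km: float
    half_extent_km: float

    def __post_init__(self):
        if self.cell_km <= 0:
            raise ValueError("cell_km must be positive")
        if self.half_extent_km < self.cell_km:
            raise ValueError("grid extent smaller than one cell")

    @property
    def n(self) -> int:
        return int(round(2.0 * self.half_extent_km / self.cell_km))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n, self.n)

    @property
    def n_cells(self) -> int:
        return self.n * self.n

    @property
    def cell_area_km2(self) -> float:
        return self.cell_km**2

    @property
    def coords_km(self) -> np.ndarray:
        """Cell-centre coordinates along one axis (shared by x and y)."""
        return -self.half_extent_km + (np.arange(self.n) + 0.5) * self.cell_km

    def cell_index(self, x, y):
        """(iy, ix) integer indices of the cells containing projected points."""
        ix = np.floor((np.asarray(x) + self.half_extent_km) / self.cell_km).astype(int)
        iy = np.floor((np.asarray(y) + self.half_extent_km) / self.cell_km).astype(int)
        return iy, ix

    def contains(self, x, y):
        h = self.half_extent_km
        return (np.asarray(x) >= -h) & (np.asarray(x) < h) & (np.asarray(y) >= -h) & (np.asarray(y) < h)

    def cell_centers_lonlat(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of shape (n, n) at cell centres."""
        c = self.coords_km
        xx, yy = np.meshgrid(c, c)  # row index = y, col index = x
        return unproject(xx, yy)

    def max_latitude(self) -> float:
        """Northernmost latitude reachable anywhere on the grid edge."""
        # Largest rho at a corner of the square extent.
        rho = np.hypot(self.half_extent_km, self.half_extent_km)
        _, lat = unproject(rho, 0.0)
        return float(lat)

    def min_covered_latitude(self) -> float:
        """Latitude up to which the grid covers *all* longitudes (inscribed circle)."""
        _, lat = unproject(self.half_extent_km, 0.0)
        return float(lat)

    def expanded(self, factor_cells: int) -> "SpatialGrid":
        return SpatialGrid(self.cell_km, self.half_extent_km + factor_cells * self.cell_km)


def default_analysis_grid(cell_km: float = 50.0) -> SpatialGrid:
    """The Southern-Ocean analysis grid: 50 km cells covering latitudes south of -30."""
    # rho at latitude -30 is 2R sin(30 deg) = R; pad by a couple of cells.
    half = float(np.ceil((EARTH_RADIUS_KM + 2 * cell_km) / cell_km) * cell_km)
    return SpatialGrid(cell_km=cell_km, half_extent_km=half)
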