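"""Regular lat/lon grid geometry and the six-field bioclimatic grid container.

The pipeline operates on co-registered gridded fields of fractional
projected cover (FPC), vegetation height (m), evergreen / tropical /
temperate fractions of vegetation, and growing degree days (GDD, base
5 degC).  Cells are half-open intervals ``[edge, edge + resolution)``;
coordinates stored on the grid are cell centres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import xarray as xr

#: Canonical variable order used throughout the package.
VARIABLES = ("fpc", "height", "evergreen", "tropical", "temperate", "gdd")

#: Physical bounds per variable.  Heights above ~130 m are not
#: hydrologically sustainable for trees, which is also the upper bound of
#: the logit height transform.  The GDD cap is only used where an
#: unbounded interval must be capped (sampling, interval distances).
PHYSICAL_BOUNDS: dict[str, tuple[float, float]] = {
    "fpc": (0.0, 1.0),
    "height": (0.0, 130.0),
    "evergreen": (0.0, 1.0),
    "tropical": (0.0, 1.0),
    "temperate": (0.0, 1.0),
    "gdd": (0.0, 10000.0),
}

EARTH_RADIUS_KM = 6371.0


class ConfigurationError(ValueError):
    """Raised for invalid geometries, scenarios or scheme configuration."""


@dataclass(frozen=True)
class GridGeometry:
    """Regular lat/lon grid described by its bounds and resolution.

    Parameters
    ----------
    lon_min, lon_max, lat_min, lat_max:
        Domain bounds in degrees.  Cell edges start at ``lon_min`` /
        ``lat_min``.
    resolution:
        Cell size in degrees (square cells).
    """

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    resolution: float

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ConfigurationError("resolution must be positive")
        if not (-90 <= self.lat_min < self.lat_max <= 90):
            raise ConfigurationError("latitude bounds must satisfy -90 <= lat_min < lat_max <= 90")
        if not self.lon_min < self.lon_max:
            raise ConfigurationError("lon_min must be < lon_max")

    @property
    def n_lon(self) -> int:
        return int(round((self.lon_max - self.lon_min) / self.resolution))

    @property
    def n_lat(self) -> int:
        return int(round((self.lat_max - self.lat_min) / self.resolution))

    @property
    def shape(self) -> tuple[int, int]:
        """(n_lat, n_lon) — row-major, latitude first."""
        return (self.n_lat, self.n_lon)

    @property
    def lons(self) -> np.ndarray:
        """Cell-centre longitudes."""
        return self.lon_min + (np.arange(self.n_lon) + 0.5) * self.resolution

    @property
    def lats(self) -> np.ndarray:
        """Cell-centre latitudes."""
        return self.lat_min + (np.arange(self.n_lat) + 0.5) * self.resolution

    def contains(self, lon: float, lat: float) -> bool:
        return (self.lon_min <= lon < self.lon_max) and (self.lat_min <= lat < self.lat_max)

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        """Return (row, col) of the cell containing a coordinate.

        Cells are half-open on their upper edges, so a point exactly on a
        shared edge belongs to the higher-index cell.
        """
        if not self.contains(lon, lat):
            raise ValueError(f"point ({lon}, {lat}) outside grid domain")
        col = int((lon - self.lon_min) / self.resolution)
        row = int((lat - self.lat_min) / self.resolution)
        return min(row, self.n_lat - 1), min(col, self.n_lon - 1)

    def cell_area_km2(self, row: int) -> float:
        """Spherical area of one cell in latitude row ``row`` (km^2).

        ``A = R^2 * dlambda * (sin(phi_top) - sin(phi_bottom))`` with
        R = 6371 km; constant along a latitude row.
        """
        phi_bot = np.deg2rad(self.lat_min + row * self.resolution)
        phi_top = np.deg2rad(self.lat_min + (row + 1) * self.resolution)
        dlam = np.deg2rad(self.resolution)
        return float(EARTH_RADIUS_KM**2 * dlam * (np.sin(phi_top) - np.sin(phi_bot)))

    def cell_areas(self) -> np.ndarray:
        """(n_lat, n_lon) array of spherical cell areas in km^2."""
        rows = np.array([self.cell_area_km2(r) for r in range(self.n_lat)])
        return np.repeat(rows[:, None], self.n_lon, axis=1)

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) cell-centre coordinate arrays of shape (n_lat, n_lon)."""
        return np.meshgrid(self.lons, self.lats)


@dataclass
class BioclimGrid:
    """Six co-registered bioclimatic fields plus a land mask.

    ``fields`` maps each name in :data:`VARIABLES` to a float array of
    shape ``geometry.shape``.  ``mask`` is True over land.
    """

    geometry: GridGeometry
    fields: dict[str, np.ndarray]
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        missing = set(VARIABLES) - set(self.fields)
        if missing:
            raise ValueError(f"missing fields: {sorted(missing)}")
        for name in VARIABLES:
            arr = np.asarray(self.fields[name], dtype=float)
            if arr.shape != self.geometry.shape:
                raise ValueError(
                    f"field {name!r} shape {arr.shape} != geometry shape {self.geometry.shape}"
                )
            self.fields[name] = arr
        if self.mask is None:
            self.mask = np.ones(self.geometry.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.geometry.shape:
                raise ValueError("mask shape does not match geometry")

    def validate_bounds(self) -> None:
        """Raise if any land cell violates its physical bounds."""
        for name in VARIABLES:
            lo, hi = PHYSICAL_BOUNDS[name]
            vals = self.fields[name][self.mask]
            if name == "gdd":
                ok = np.all(vals >= lo)
            elif name == "height":
                ok = np.all((vals >= lo) & (vals < hi))
            else:
                ok = np.all((vals >= lo) & (vals <= hi))
            if not ok:
                raise ValueError(f"field {name!r} violates physical bounds")

    def values_at(self, row: int, col: int) -> dict[str, float]:
        return {name: float(self.fields[name][row, col]) for name in VARIABLES}

    def copy(self) -> "BioclimGrid":
        return BioclimGrid(
            geometry=self.geometry,
            fields={k: v.copy() for k, v in self.fields.items()},
            mask=self.mask.copy(),
        )

    # --- IO -----------------------------------------------------------

    def to_dataset(self, attrs: Mapping[str, object] | None = None) -> xr.Dataset:
        """CF-style dataset: one variable per field, lat/lon coordinates."""
        coords = {"lat": ("lat", self.geometry.lats), "lon": ("lon", self.geometry.lons)}
        data = {name: (("lat", "lon"), self.fields[name]) for name in VARIABLES}
        data["land_mask"] = (("lat", "lon"), self.mask.astype(np.int8))
        ds = xr.Dataset(data, coords=coords)
        ds["lat"].attrs.update(units="degrees_north", standard_name="latitude")
        ds["lon"].attrs.update(units="degrees_east", standard_name="longitude")
        ds.attrs["resolution"] = self.geometry.resolution
        ds.attrs["bounds"] = [
            self.geometry.lon_min,
            self.geometry.lon_max,
            self.geometry.lat_min,
            self.geometry.lat_max,
        ]
        if attrs:
            ds.attrs.update({k: v for k, v in attrs.items() if v is not None})
        return ds

    def to_netcdf(self, path, attrs: Mapping[str, object] | None = None) -> None:
        self.to_dataset(attrs=attrs).to_netcdf(path, engine="scipy")

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "BioclimGrid":
        lats = np.asarray(ds["lat"].values, dtype=float)
        lons = np.asarray(ds["lon"].values, dtype=float)
        res = float(ds.attrs.get("resolution", np.diff(lons).mean()))
        geom = GridGeometry(
            lon_min=float(lons[0] - res / 2),
            lon_max=float(lons[-1] + res / 2),
            lat_min=float(lats[0] - res / 2),
            lat_max=float(lats[-1] + res / 2),
            resolution=res,
        )
        fields = {name: np.asarray(ds[name].values, dtype=float) for name in VARIABLES}
        mask = (
            np.asarray(ds["land_mask"].values).astype(bool)
            if "land_mask" in ds
            else np.ones(geom.shape, dtype=bool)
        )
        return cls(geometry=geom, fields=fields, mask=mask)

    @classmethod
    def from_netcdf(cls, path) -> "BioclimGrid":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls.from_dataset(ds.load())


def constant_grid(geometry: GridGeometry, values: Mapping[str, float]) -> BioclimGrid:
    """Grid with every field constant — handy for tests and null models."""
    fields = {name: np.full(geometry.shape, float(values[name])) for name in VARIABLES}
    return BioclimGrid(geometry=geometry, fields=fields)
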