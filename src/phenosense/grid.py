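"""Gridded monthly climate container and per-cell covariate extraction.

The grid mirrors the layout of 0.5-degree monthly climate time series (CRU TS
style): variables ``tmp`` (monthly mean temperature, degC), ``tmn`` (monthly
minimum temperature, degC) and ``pre`` (monthly precipitation, mm) on
dimensions (time, lat, lon), with cell centers on the regular 0.5-degree mesh
(offsets of 0.25). A cell with center ``c`` covers the half-open interval
``[c - 0.25, c + 0.25)`` in each coordinate, so a point lying exactly on a
shared boundary belongs to the adjacent higher cell.

Long-term climate normals per cell:

* MAT -- mean over years of the annual mean of the 12 monthly minimum
  temperatures (degC), 1901-2021.
* IVT -- sample standard deviation (denominator n-1) of those annual means
  (s.d. degC), i.e. interannual variability in temperature.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import xarray as xr

CELL_SIZE = 0.5
#: Years spanned by the long-term record used for MAT/IVT.
CLIMATE_YEARS = (1901, 2021)


class GridLookupError(KeyError):
    """Coordinate falls outside the grid, or addresses an all-missing cell."""


def _cell_center(coord: float) -> float:
    """Center of the 0.5-degree cell containing ``coord`` (half-open bounds)."""
    return np.floor(coord / CELL_SIZE) * CELL_SIZE + CELL_SIZE / 2.0


class ClimateGrid:
    """Monthly climate fields on a regular 0.5-degree mesh.

    Parameters
    ----------
    ds : xarray.Dataset
        Dataset with dims ``(time, lat, lon)``, data variables ``tmp``,
        ``tmn``, ``pre``, integer auxiliary coordinates ``year`` and
        ``month`` along ``time``, and an integer variable
        ``continent_code`` on ``(lat, lon)`` whose mapping is stored in its
        ``labels`` attribute (comma-separated, index order).
    """

    VARIABLES = ("tmp", "tmn", "pre")

    def __init__(self, ds: xr.Dataset):
        for var in self.VARIABLES:
            if var not in ds:
                raise ValueError(f"climate dataset is missing variable {var!r}")
        for coord in ("year", "month"):
            if coord not in ds.coords:
                raise ValueError(f"climate dataset is missing coordinate {coord!r}")
        self.ds = ds
        self._lat_index = {round(float(v), 6): i for i, v in enumerate(ds.lat.values)}
        self._lon_index = {round(float(v), 6): i for i, v in enumerate(ds.lon.values)}
        self._mat = None
        self._ivt = None
        self._valid = None
        self._wcache: dict = {}

    # -- basic geometry ----------------------------------------------------
    @property
    def lats(self) -> np.ndarray:
        return self.ds.lat.values

    @property
    def lons(self) -> np.ndarray:
        return self.ds.lon.values

    @property
    def years(self) -> np.ndarray:
        return np.unique(self.ds.year.values)

    @property
    def continent_labels(self) -> list[str]:
        return self.ds["continent_code"].attrs["labels"].split(",")

    def continent_of(self, cell: tuple[int, int]) -> str:
        code = int(self.ds["continent_code"].values[cell])
        return self.continent_labels[code]

    def locate_cell(
        self, latitude: float, longitude: float, record: object | None = None
    ) -> tuple[int, int]:
        """Index ``(ilat, ilon)`` of the cell containing a point.

        Half-open cell bounds: a point on a shared edge maps to the higher
        cell. Raises :class:`GridLookupError` for points outside the grid or
        addressing a cell with an entirely missing series, naming ``record``
        in the message when given.
        """
        clat = round(_cell_center(latitude), 6)
        clon = round(_cell_center(longitude), 6)
        who = "" if record is None else f" (record {record})"
        if clat not in self._lat_index or clon not in self._lon_index:
            raise GridLookupError(
                f"point ({latitude}, {longitude}) is outside the climate grid{who}"
            )
        cell = (self._lat_index[clat], self._lon_index[clon])
        if self._valid is None:
            self._valid = ~np.isnan(self.ds["tmn"].values).all(axis=0)
        if not self._valid[cell]:
            raise GridLookupError(
                f"climate cell at ({clat}, {clon}) has an all-missing series{who}"
            )
        return cell

    def locate_cells(self, latitudes, longitudes, ids=None) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized :meth:`locate_cell` for aligned coordinate arrays."""
        latitudes = np.asarray(latitudes, dtype=float)
        longitudes = np.asarray(longitudes, dtype=float)
        clat = np.round(np.floor(latitudes / CELL_SIZE) * CELL_SIZE + CELL_SIZE / 2, 6)
        clon = np.round(np.floor(longitudes / CELL_SIZE) * CELL_SIZE + CELL_SIZE / 2, 6)
        lats = np.round(self.lats.astype(float), 6)
        lons = np.round(self.lons.astype(float), 6)
        ilat = np.searchsorted(lats, clat)
        ilon = np.searchsorted(lons, clon)
        ok = (
            (ilat < lats.size)
            & (ilon < lons.size)
            & (lats[np.minimum(ilat, lats.size - 1)] == clat)
            & (lons[np.minimum(ilon, lons.size - 1)] == clon)
        )
        if not ok.all():
            k = int(np.argmin(ok))
            who = "" if ids is None else f" (record {np.asarray(ids)[k]})"
            raise GridLookupError(
                f"point ({latitudes[k]}, {longitudes[k]}) is outside the climate grid{who}"
            )
        if self._valid is None:
            self._valid = ~np.isnan(self.ds["tmn"].values).all(axis=0)
        bad = ~self._valid[ilat, ilon]
        if bad.any():
            k = int(np.argmax(bad))
            who = "" if ids is None else f" (record {np.asarray(ids)[k]})"
            raise GridLookupError(
                f"climate cell at ({clat[k]}, {clon[k]}) has an all-missing series{who}"
            )
        return ilat, ilon

    # -- per-cell extraction ----------------------------------------------
    def window_mean_field(self, variable: str, year: int, window) -> np.ndarray:
        """Seasonal-window mean of ``variable`` for every cell (cached)."""
        window = tuple(window)
        key = (variable, int(year), window)
        if key not in self._wcache:
            years = self.ds.year.values
            months = self.ds.month.values
            mask = (years == year) & np.isin(months, window)
            if mask.sum() != len(window):
                raise ValueError(
                    f"grid lacks months {window} of year {year} "
                    f"(found {int(mask.sum())} of {len(window)})"
                )
            self._wcache[key] = self.ds[variable].values[mask].mean(axis=0)
        return self._wcache[key]

    def seasonal_mean(
        self, variable: str, cell: tuple[int, int], year: int, window: Iterable[int]
    ) -> float:
        """Mean of ``variable`` over the given months of one year at a cell."""
        window = tuple(window)
        years = self.ds.year.values
        months = self.ds.month.values
        mask = (years == year) & np.isin(months, window)
        if mask.sum() != len(window):
            raise ValueError(
                f"grid lacks months {window} of year {year} "
                f"(found {int(mask.sum())} of {len(window)})"
            )
        vals = self.ds[variable].values[mask, cell[0], cell[1]]
        if np.isnan(vals).any():
            raise ValueError(f"missing monthly values in {variable} at cell {cell}, year {year}")
        return float(vals.mean())

    def _annual_min_means(self) -> np.ndarray:
        """Annual mean of monthly minimum temperature, shape (nyears, nlat, nlon)."""
        tmn = self.ds["tmn"]
        grouped = tmn.groupby(self.ds.year).mean("time")
        return grouped.values

    def mat_field(self) -> np.ndarray:
        """MAT (degC) for every cell; NaN where the series is missing."""
        if self._mat is None:
            self._mat = self._annual_min_means().mean(axis=0)
        return self._mat

    def ivt_field(self) -> np.ndarray:
        """IVT (s.d. degC) for every cell, sample (n-1) standard deviation."""
        if self._ivt is None:
            self._ivt = self._annual_min_means().std(axis=0, ddof=1)
        return self._ivt

    def compute_mat(self, cell: tuple[int, int]) -> float:
        """Long-term mean of annual mean monthly minimum temperature (degC)."""
        val = self.mat_field()[cell]
        if np.isnan(val):
            raise ValueError(f"cell {cell} has missing minimum-temperature months")
        return float(val)

    def compute_ivt(self, cell: tuple[int, int]) -> float:
        """Interannual s.d. of annual mean monthly minimum temperature."""
        val = self.ivt_field()[cell]
        if np.isnan(val):
            raise ValueError(f"cell {cell} has missing minimum-temperature months")
        return float(val)

    # -- I/O ---------------------------------------------------------------
    def to_netcdf(self, path) -> None:
        """Write the grid as a classic NetCDF file (CF-style dims lat/lon/time)."""
        self.ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "ClimateGrid":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls(ds.load())
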