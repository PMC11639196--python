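"""Synthetic climate grids and phenology observations with known truth.

The generator emulates the study conditions of a two-continent community
science phenology dataset: six herbaceous species observed in Eurasia and
North America over 2017-2019, with MAT declining and IVT increasing with
latitude, Eurasia warmer (+4.91 degC) and less variable (-0.22 s.d.) than
North America, and observation day of year produced by a linear model whose
temperature slope depends on MAT and IVT through a known bilinear
"sensitivity surface":

    b(MAT, IVT) = gamma0 + gammaM*MAT + gammaV*IVT + gammaMV*MAT*IVT

Because the data-generating process lies exactly inside the span of the
global interaction model fitted by the analysis modules, estimated marginal
slopes admit honest confidence intervals against ``truth_slope`` -- the basis
of the package's parameter-recovery tests.

Monthly series are built as a sinusoidal seasonal cycle plus an annual
anomaly shared by all months of a year within a cell (which sets IVT) plus
independent monthly noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .grid import CELL_SIZE, ClimateGrid
from .species import (
    PHENOPHASES,
    REPRODUCTIVE_PHENOPHASES,
    SPECIES,
    season_window,
)


@dataclass(frozen=True)
class RegionSpec:
    """Spatial/temporal extent of a synthetic grid.

    Two disjoint longitude bands represent the continents; latitudes are
    shared. Bounds must be multiples of 0.5 so cells align with the mesh.
    """

    lat_range: tuple[float, float] = (35.0, 65.0)
    lon_bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "North America": (-95.0, -80.0),
            "Eurasia": (0.0, 15.0),
        }
    )
    years: tuple[int, int] = (1901, 2021)

    def validate(self) -> None:
        if self.lat_range[1] <= self.lat_range[0]:
            raise ValueError("latitude extent must be positive")
        for name, (lo, hi) in self.lon_bands.items():
            if hi <= lo:
                raise ValueError(f"longitude extent of {name!r} must be positive")
        bands = sorted(self.lon_bands.values())
        for (_, hi), (lo, _) in zip(bands, bands[1:]):
            if lo < hi:
                raise ValueError("longitude bands must be disjoint")
        if self.years[1] < self.years[0]:
            raise ValueError("year range must be non-empty")


@dataclass(frozen=True)
class ClimateGradientParams:
    """Latitudinal/continental structure of the synthetic climate.

    Defaults mimic the observed gradients of the study region: MAT cooling by
    0.45 degC per degree latitude, IVT increasing by 0.02 s.d. per degree
    latitude, Eurasia on average 4.91 degC warmer and 0.22 s.d. less variable
    than North America.
    """

    ref_lat: float = 50.0
    mat_ref: float = 2.5           # degC, North America at ref_lat
    mat_lapse: float = -0.45       # degC per degree latitude
    eurasia_mat_offset: float = 4.91
    ivt_ref: float = 0.92          # s.d. degC, North America at ref_lat
    ivt_lat_gain: float = 0.02     # s.d. per degree latitude
    eurasia_ivt_offset: float = -0.22
    seasonal_amplitude: float = 10.0   # degC, peak-to-mean of the annual cycle
    diurnal_offset: float = 4.5        # degC, tmp minus tmn
    monthly_noise_sd: float = 0.8      # degC, independent month-to-month noise
    precip_mean: float = 60.0          # mm/month
    precip_amplitude: float = 20.0
    precip_annual_sd: float = 10.0
    precip_monthly_sd: float = 15.0


# Known sensitivity surface and day-of-year model. The bilinear gamma
# coefficients pass through corner slopes (-1.48, -1.14, -2.36, -4.26)
# days/degC at (MAT, IVT) = (-5, 0.4), (-5, 1.2), (15, 0.4), (15, 1.2); at the
# sample-mean climate (~5 degC, ~0.8 s.d.) the surface evaluates to about
# -2.3 days/degC with an average MAT trend of about -0.10 per degC MAT.
@dataclass(frozen=True)
class SensitivityTruth:
    """Parametric truth used to generate observation day of year."""

    gamma0: float = -1.59        # days/degC at MAT=0, IVT=0
    gamma_mat: float = 0.012     # change in slope per degC MAT
    gamma_ivt: float = -0.275    # change in slope per s.d. IVT
    gamma_mat_ivt: float = -0.14  # interaction, per degC * s.d.
    beta_precip: float = 0.03    # days per mm standardized precipitation
    #: Per-species additive offsets to the temperature slope (sum to zero so
    #: the species-averaged surface equals the bilinear form above).
    species_slope_offsets: dict[str, float] = field(
        default_factory=lambda: {
            "Tussilago farfara": -1.09,
            "Ficaria verna": -0.35,
            "Alliaria petiolata": 1.21,
            "Cirsium arvense": 0.45,
            "Daucus carota": 0.08,
            "Lythrum salicaria": -0.30,
        }
    )
    #: Baseline DOY per species (days) at the anchor climate.
    species_baselines: dict[str, float] = field(
        default_factory=lambda: {
            "Tussilago farfara": 80.0,
            "Ficaria verna": 95.0,
            "Alliaria petiolata": 115.0,
            "Cirsium arvense": 175.0,
            "Daucus carota": 185.0,
            "Lythrum salicaria": 195.0,
        }
    )
    phenophase_offsets: dict[str, float] = field(
        default_factory=lambda: {
            "vegetative": -15.0,
            "budding": 0.0,
            "flowering": 10.0,
            "fruiting": 25.0,
        }
    )
    #: Baseline climatology: phenology advances with site MAT at this rate
    #: (days/degC), anchored at ``mat_anchor``. Routing the poleward delay
    #: through MAT keeps the generating process inside the analysis model's
    #: span while producing a realistic latitudinal trend in DOY.
    mat_doy_slope: float = -1.09
    mat_anchor: float = 5.0
    noise_sd: float = 22.0       # residual day-of-year noise (days)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SensitivityTruth":
        return cls(**d)


def truth_slope(truth: SensitivityTruth, mat, ivt, species: str | None = None):
    """True temperature sensitivity (days/degC) at given MAT and IVT."""
    mat = np.asarray(mat, dtype=float)
    ivt = np.asarray(ivt, dtype=float)
    b = (
        truth.gamma0
        + truth.gamma_mat * mat
        + truth.gamma_ivt * ivt
        + truth.gamma_mat_ivt * mat * ivt
    )
    if species is not None:
        b = b + truth.species_slope_offsets[species]
    if b.ndim == 0:
        return float(b)
    return b


def save_truth(truth: SensitivityTruth, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(truth.to_dict(), fh, sort_keys=True)


def load_truth(path) -> SensitivityTruth:
    with open(path) as fh:
        return SensitivityTruth.from_dict(yaml.safe_load(fh))


def _band_centers(lo: float, hi: float) -> np.ndarray:
    n = int(round((hi - lo) / CELL_SIZE))
    return lo + CELL_SIZE / 2.0 + CELL_SIZE * np.arange(n)


def generate_climate_grid(
    region: RegionSpec | None = None,
    gradients: ClimateGradientParams | None = None,
    seed: int = 0,
) -> ClimateGrid:
    """Generate a synthetic monthly climate grid with configured gradients.

    The realized per-cell MAT and IVT (as computed by
    :class:`~phenosense.grid.ClimateGrid`) carry the configured latitudinal
    slopes and continental offsets up to the sampling noise of a finite
    (121-year by default) series.
    """
    region = region or RegionSpec()
    gradients = gradients or ClimateGradientParams()
    region.validate()
    if gradients.ivt_ref <= 0:
        raise ValueError("interannual variability parameter must be positive")

    rng = np.random.default_rng(seed)

    lats = _band_centers(*region.lat_range)
    band_lons = {name: _band_centers(lo, hi) for name, (lo, hi) in region.lon_bands.items()}
    names = sorted(region.lon_bands, key=lambda n: region.lon_bands[n][0])
    lons = np.concatenate([band_lons[n] for n in names])
    codes = np.concatenate(
        [np.full(band_lons[n].size, i, dtype=np.int8) for i, n in enumerate(names)]
    )

    nlat, nlon = lats.size, lons.size
    years = np.arange(region.years[0], region.years[1] + 1)
    nyears = years.size
    month = np.tile(np.arange(1, 13), nyears)
    year = np.repeat(years, 12)
    ntime = year.size

    is_eurasia = np.array([names[c] == "Eurasia" for c in codes])
    mat_target = (
        gradients.mat_ref
        + gradients.mat_lapse * (lats[:, None] - gradients.ref_lat)
        + np.where(is_eurasia[None, :], gradients.eurasia_mat_offset, 0.0)
    )
    ivt_target = (
        gradients.ivt_ref
        + gradients.ivt_lat_gain * (lats[:, None] - gradients.ref_lat)
        + np.where(is_eurasia[None, :], gradients.eurasia_ivt_offset, 0.0)
    )
    monthly_var = gradients.monthly_noise_sd**2 / 12.0
    sigma_year_sq = ivt_target**2 - monthly_var
    if np.any(ivt_target <= 0) or np.any(sigma_year_sq <= 0):
        raise ValueError(
            "configured IVT is too small to realize: the interannual anomaly "
            "variance (IVT^2 - monthly_noise_sd^2/12) must be positive everywhere"
        )
    sigma_year = np.sqrt(sigma_year_sq)

    cycle = np.cos(2 * np.pi * (month - 7) / 12.0)  # +1 in July, -1 in January
    annual = rng.standard_normal((nyears, nlat, nlon)) * sigma_year
    annual_rep = np.repeat(annual, 12, axis=0)
    tmn = (
        mat_target[None, :, :]
        + gradients.seasonal_amplitude * cycle[:, None, None]
        + annual_rep
        + rng.normal(0.0, gradients.monthly_noise_sd, (ntime, nlat, nlon))
    ).astype(np.float32)
    tmp = tmn + np.float32(gradients.diurnal_offset)

    pre_cycle = np.cos(2 * np.pi * (month - 10) / 12.0)
    pre_annual = np.repeat(
        rng.normal(0.0, gradients.precip_annual_sd, (nyears, nlat, nlon)), 12, axis=0
    )
    pre = (
        gradients.precip_mean
        + gradients.precip_amplitude * pre_cycle[:, None, None]
        + pre_annual
        + rng.normal(0.0, gradients.precip_monthly_sd, (ntime, nlat, nlon))
    )
    pre = np.clip(pre, 0.0, None).astype(np.float32)

    time = np.arange(ntime)
    continent = xr.DataArray(
        np.broadcast_to(codes, (nlat, nlon)).copy(),
        dims=("lat", "lon"),
        attrs={"labels": ",".join(names)},
    )
    ds = xr.Dataset(
        {
            "tmp": (("time", "lat", "lon"), tmp),
            "tmn": (("time", "lat", "lon"), tmn),
            "pre": (("time", "lat", "lon"), pre),
            "continent_code": continent,
        },
        coords={
            "time": time,
            "lat": lats,
            "lon": lons,
            "year": ("time", year),
            "month": ("time", month),
        },
        attrs={"title": "synthetic 0.5-degree monthly climate", "seed": int(seed)},
    )
    ds["tmp"].attrs = {"units": "degC", "long_name": "monthly mean temperature"}
    ds["tmn"].attrs = {"units": "degC", "long_name": "monthly minimum temperature"}
    ds["pre"].attrs = {"units": "mm", "long_name": "monthly precipitation"}
    return ClimateGrid(ds)


def _window_field(grid: ClimateGrid, variable: str, year: int, window) -> np.ndarray:
    years = grid.ds.year.values
    months = grid.ds.month.values
    mask = (years == year) & np.isin(months, tuple(window))
    return grid.ds[variable].values[mask].mean(axis=0)


def generate_observations(
    grid: ClimateGrid,
    truth: SensitivityTruth | None = None,
    n_per_species_continent: int = 2000,
    seed: int = 0,
    years: tuple[int, int] = (2017, 2019),
    species: tuple[str, ...] | None = None,
    continent_weights: dict[str, float] | None = None,
    vegetative_fraction: float = 0.0,
) -> pd.DataFrame:
    """Simulate a phenology observation table from a grid and a truth.

    Each record receives a uniformly random cell on its continent, uniform
    coordinates within the cell, a uniform year and phenophase, and a day of
    year drawn from the linear truth model::

        DOY = baseline(species, phenophase) + mat_doy_slope*(MAT - anchor)
              + [b(MAT, IVT) + species offset] * Tstd + beta_precip * Pstd
              + N(0, noise_sd)

    rounded and clamped to [1, 365]. Tstd/Pstd are the seasonal-window means
    of the observation year, mean-centred within species -- the same
    standardization the analysis pipeline applies.

    ``continent_weights`` optionally reallocates each species' total sample
    (2 * n) across continents by probability weight; by default sampling is
    balanced, matching the study design.
    """
    truth = truth or SensitivityTruth()
    if n_per_species_continent < 1:
        raise ValueError("n_per_species_continent must be >= 1")
    species = tuple(species) if species is not None else SPECIES
    unknown = set(species) - set(SPECIES)
    if unknown:
        raise ValueError(f"unknown species: {sorted(unknown)}")
    if grid.lats.size == 0 or grid.lons.size == 0:
        raise ValueError("climate grid is empty")
    if not 0.0 <= vegetative_fraction < 1.0:
        raise ValueError("vegetative_fraction must be in [0, 1)")

    rng = np.random.default_rng(seed)
    labels = grid.continent_labels
    codes2d = grid.ds["continent_code"].values
    cont_cells = {
        name: np.argwhere(codes2d == i) for i, name in enumerate(labels)
    }
    for name, cells in cont_cells.items():
        if cells.size == 0:
            raise ValueError(f"grid has no cells on continent {name!r}")

    obs_years = np.arange(years[0], years[1] + 1)
    windows = {"spring": (1, 2, 3), "summer": (3, 4, 5)}
    tmp_fields = {
        (g, y): _window_field(grid, "tmp", y, w)
        for g, w in windows.items()
        for y in obs_years
    }
    pre_fields = {
        (g, y): _window_field(grid, "pre", y, w)
        for g, w in windows.items()
        for y in obs_years
    }
    mat_field = grid.mat_field()
    ivt_field = grid.ivt_field()

    if continent_weights is None:
        alloc = {name: n_per_species_continent for name in labels}
    else:
        w = np.array([continent_weights.get(name, 0.0) for name in labels], float)
        if w.sum() <= 0:
            raise ValueError("continent weights must have positive sum")
        w = w / w.sum()
        total = n_per_species_continent * len(labels)
        counts = rng.multinomial(total, w)
        alloc = dict(zip(labels, counts))

    rows = []
    for sp in species:
        group = "spring" if season_window(sp) == (1, 2, 3) else "summer"
        for cont in labels:
            n = int(alloc[cont])
            if n == 0:
                continue
            cells = cont_cells[cont]
            pick = cells[rng.integers(0, len(cells), n)]
            ilat, ilon = pick[:, 0], pick[:, 1]
            lat = grid.lats[ilat] + rng.uniform(-CELL_SIZE / 2, CELL_SIZE / 2, n)
            lon = grid.lons[ilon] + rng.uniform(-CELL_SIZE / 2, CELL_SIZE / 2, n)
            yr = rng.choice(obs_years, n)
            if vegetative_fraction > 0:
                veg = rng.random(n) < vegetative_fraction
                phase = np.where(
                    veg, "vegetative", rng.choice(REPRODUCTIVE_PHENOPHASES, n)
                )
            else:
                phase = rng.choice(REPRODUCTIVE_PHENOPHASES, n)
            t_seas = np.array(
                [tmp_fields[(group, y)][i, j] for y, i, j in zip(yr, ilat, ilon)]
            )
            p_seas = np.array(
                [pre_fields[(group, y)][i, j] for y, i, j in zip(yr, ilat, ilon)]
            )
            rows.append(
                pd.DataFrame(
                    {
                        "species": sp,
                        "latitude": lat,
                        "longitude": lon,
                        "continent": cont,
                        "year": yr,
                        "phenophase": phase,
                        "_t_seas": t_seas,
                        "_p_seas": p_seas,
                        "_mat": mat_field[ilat, ilon],
                        "_ivt": ivt_field[ilat, ilon],
                    }
                )
            )
    df = pd.concat(rows, ignore_index=True)

    # seasonal anomalies, centred within species as the analysis does
    df["_t_std"] = df["_t_seas"] - df.groupby("species")["_t_seas"].transform("mean")
    df["_p_std"] = df["_p_seas"] - df.groupby("species")["_p_seas"].transform("mean")

    slope = truth_slope(truth, df["_mat"].values, df["_ivt"].values) + df[
        "species"
    ].map(truth.species_slope_offsets).values
    baseline = (
        df["species"].map(truth.species_baselines).values
        + df["phenophase"].map(truth.phenophase_offsets).values
        + truth.mat_doy_slope * (df["_mat"].values - truth.mat_anchor)
    )
    doy = (
        baseline
        + slope * df["_t_std"].values
        + truth.beta_precip * df["_p_std"].values
        + rng.normal(0.0, truth.noise_sd, len(df))
    )
    doy = np.clip(np.rint(doy), 1, 365).astype(int)

    date = pd.to_datetime(
        df["year"].astype(str) + "-" + pd.Series(doy).astype(str), format="%Y-%j"
    )
    out = pd.DataFrame(
        {
            "id": [f"syn-{i:06d}" for i in range(len(df))],
            "species": df["species"],
            "date": date.dt.date.astype(str),
            "latitude": df["latitude"].round(5),
            "longitude": df["longitude"].round(5),
            "continent": df["continent"],
            "phenophase": pd.Categorical(df["phenophase"], categories=PHENOPHASES),
        }
    )
    return out
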