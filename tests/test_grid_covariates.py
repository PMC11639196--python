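"""Cell lookup, seasonal means, MAT/IVT normals and standardization."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from phenosense.covariates import ClimateCovariateExtractor, attach_covariates, standardize
from phenosense.grid import ClimateGrid, GridLookupError


def make_grid(tmn_annual, lats=(50.25,), lons=(10.25,)):
    """Grid from per-year scalar minimum temperatures (constant within a year)."""
    tmn_annual = np.asarray(tmn_annual, dtype=float)
    nyears = tmn_annual.size
    years = np.repeat(np.arange(2001, 2001 + nyears), 12)
    months = np.tile(np.arange(1, 13), nyears)
    shape = (nyears * 12, len(lats), len(lons))
    tmn = np.broadcast_to(np.repeat(tmn_annual, 12)[:, None, None], shape).copy()
    ds = xr.Dataset(
        {
            "tmp": (("time", "lat", "lon"), tmn + 4.0),
            "tmn": (("time", "lat", "lon"), tmn),
            "pre": (("time", "lat", "lon"), np.full(shape, 50.0)),
            "continent_code": (
                ("lat", "lon"),
                np.zeros((len(lats), len(lons)), dtype=np.int8),
                {"labels": "Eurasia"},
            ),
        },
        coords={
            "time": np.arange(nyears * 12),
            "lat": list(lats),
            "lon": list(lons),
            "year": ("time", years),
            "month": ("time", months),
        },
    )
    return ClimateGrid(ds)


class TestLocateCell:
    def test_point_at_center(self, small_grid):
        lat, lon = small_grid.lats[3], small_grid.lons[2]
        assert small_grid.locate_cell(lat, lon) == (3, 2)

    def test_shared_boundary_goes_to_higher_cell(self, small_grid):
        # -87.5 is the edge between cells centered -87.75 and -87.25
        cell = small_grid.locate_cell(50.0, -87.5)
        assert small_grid.lons[cell[1]] == pytest.approx(-87.25)
        assert small_grid.lats[cell[0]] == pytest.approx(50.25)

    def test_outside_grid_is_error(self, small_grid):
        with pytest.raises(GridLookupError, match="outside"):
            small_grid.locate_cell(20.0, 10.0)

    def test_all_missing_cell_names_record(self, small_grid):
        ds = small_grid.ds.copy(deep=True)
        ds["tmn"].values[:, 0, 0] = np.nan
        gappy = ClimateGrid(ds)
        lat, lon = gappy.lats[0], gappy.lons[0]
        with pytest.raises(GridLookupError, match="rec-42"):
            gappy.locate_cell(lat, lon, record="rec-42")


class TestSeasonalMean:
    def test_hand_values(self):
        g = make_grid([0.0, 0.0])
        g.ds["tmp"].values[:, 0, 0] = 0.0
        assert g.seasonal_mean("tmp", (0, 0), 2001, (1, 2, 3)) == 0.0
        # months Jan..Mar of 2002 set to 1, 2, 3
        g.ds["tmp"].values[12:15, 0, 0] = [1.0, 2.0, 3.0]
        assert g.seasonal_mean("tmp", (0, 0), 2002, (1, 2, 3)) == pytest.approx(2.0)

    def test_missing_year_is_error(self):
        g = make_grid([0.0])
        with pytest.raises(ValueError, match="lacks months"):
            g.seasonal_mean("tmp", (0, 0), 1999, (1, 2, 3))

    def test_file_fixture_matches_hand_read(self, small_grid, tmp_path):
        """Value read through the CRU-style file equals the raw stored mean."""
        path = tmp_path / "clim.nc"
        small_grid.to_netcdf(path)
        g = ClimateGrid.from_netcdf(path)
        mask = (g.ds.year.values == 2018) & np.isin(g.ds.month.values, (3, 4, 5))
        hand = g.ds["tmp"].values[mask, 4, 1].mean()
        assert g.seasonal_mean("tmp", (4, 1), 2018, (3, 4, 5)) == pytest.approx(hand, abs=1e-9)


class TestClimateNormals:
    def test_constant_series(self):
        g = make_grid([5.0] * 6)
        assert g.compute_mat((0, 0)) == pytest.approx(5.0)
        assert g.compute_ivt((0, 0)) == pytest.approx(0.0)

    def test_alternating_annual_values_hand_sd(self):
        # annual means -1, +1, -1, +1: MAT=0, sample s.d. = sqrt(4/3)
        g = make_grid([-1.0, 1.0, -1.0, 1.0])
        assert g.compute_mat((0, 0)) == pytest.approx(0.0)
        assert g.compute_ivt((0, 0)) == pytest.approx(np.sqrt(4.0 / 3.0))
        assert g.compute_ivt((0, 0)) == pytest.approx(1.1547, abs=1e-4)

    def test_month_order_invariance(self, rng):
        vals = rng.normal(0, 5, 36)
        g = make_grid([0.0, 0.0, 0.0])
        g.ds["tmn"].values[:, 0, 0] = vals
        mat0, ivt0 = g.compute_mat((0, 0)), g.compute_ivt((0, 0))
        shuffled = vals.reshape(3, 12).copy()
        for row in shuffled:
            rng.shuffle(row)
        g2 = make_grid([0.0, 0.0, 0.0])
        g2.ds["tmn"].values[:, 0, 0] = shuffled.ravel()
        assert g2.compute_mat((0, 0)) == pytest.approx(mat0)
        assert g2.compute_ivt((0, 0)) == pytest.approx(ivt0)

    def test_constant_shift_moves_mat_not_ivt(self, rng):
        vals = rng.normal(0, 5, 24)
        g = make_grid([0.0, 0.0])
        g.ds["tmn"].values[:, 0, 0] = vals
        g2 = make_grid([0.0, 0.0])
        g2.ds["tmn"].values[:, 0, 0] = vals + 3.0
        assert g2.compute_mat((0, 0)) == pytest.approx(g.compute_mat((0, 0)) + 3.0)
        assert g2.compute_ivt((0, 0)) == pytest.approx(g.compute_ivt((0, 0)))

    def test_synthetic_ivt_spans_configured_band(self, default_grid):
        ivt = default_grid.ivt_field()
        assert ivt.min() > 0.3 and ivt.max() < 1.5
        assert ivt.min() < 0.45 and ivt.max() > 1.1


class TestStandardize:
    def test_group_means_are_zero(self, rng):
        vals = rng.normal(10, 3, 200)
        groups = rng.choice(["a", "b", "c"], 200)
        out = standardize(vals, groups)
        for grp in "abc":
            assert abs(out[groups == grp].mean()) < 1e-9

    def test_simple_cases(self):
        assert np.allclose(standardize([5, 5, 5], ["g"] * 3), [0, 0, 0])
        assert np.allclose(standardize([1, 3], ["g", "g"]), [-1, 1])

    def test_independent_groups_leave_grand_mean_nonzero(self):
        out = standardize([0.0, 1.0, 10.0], ["a", "a", "b"])
        assert np.allclose(out, [-0.5, 0.5, 0.0])
        assert abs(np.mean(standardize([0, 2, 9], ["a", "a", "b"]))) < 1e-9  # equal groups
        # unequal group sizes: grand mean of input != group means, output still 0 per group
        assert out[2] == 0.0

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            standardize([], [])


class TestCovariateExtraction:
    def test_attach_covariates_centers_within_species(self, small_covariates):
        g = small_covariates.groupby("species")
        assert np.allclose(g["t_std"].mean(), 0.0, atol=1e-9)
        assert np.allclose(g["p_std"].mean(), 0.0, atol=1e-9)
        assert (small_covariates["ivt"] >= 0).all()

    def test_sklearn_extractor_matches_function(self, small_grid, small_covariates):
        obs = small_covariates[
            ["id", "species", "date", "latitude", "longitude", "continent", "phenophase"]
        ]
        ext = ClimateCovariateExtractor(grid=small_grid).fit(obs)
        out = ext.transform(obs)
        assert np.allclose(out["t_std"], small_covariates["t_std"], atol=1e-9)
        assert np.allclose(out["mat"], small_covariates["mat"])
        # sklearn param plumbing
        assert ext.get_params()["grouping"] == "species"

    def test_grouping_option_changes_centering(self, small_grid, small_covariates):
        obs = small_covariates[
            ["id", "species", "date", "latitude", "longitude", "continent", "phenophase"]
        ]
        out = attach_covariates(obs, small_grid, grouping="species_continent")
        g = out.groupby(["species", "continent"])
        assert np.allclose(g["t_std"].mean(), 0.0, atol=1e-9)
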