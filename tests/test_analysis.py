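"""Sensitivity surfaces, projection, ranges and trend profiles."""

import numpy as np
import pandas as pd
import pytest

from phenosense.analysis import (
    intraspecific_range,
    interspecific_range,
    map_sensitivity,
    mat_trend_profile,
    precipitation_sensitivity,
    sensitivity_surface,
)
from phenosense.emm import make_reference_grid, marginal_slope, slope_trend


class TestSurfaceGeometry:
    def test_fine_grid_node_count(self, global_fit):
        surf = sensitivity_surface(global_fit)
        assert surf.n_nodes == 101 * 17 == 1717
        assert surf.mat_axis.size == 101 and surf.ivt_axis.size == 17

    def test_coarse_grid_node_count(self, global_fit):
        surf = sensitivity_surface(global_fit, mat_step=1.0, ivt_step=0.1)
        assert surf.n_nodes == 21 * 9 == 189

    def test_step_must_divide_range(self, global_fit):
        with pytest.raises(ValueError, match="does not divide"):
            sensitivity_surface(global_fit, mat_step=0.3)

    def test_nodes_match_pointwise_marginal_slopes(self, global_fit):
        surf = sensitivity_surface(global_fit, mat_step=5.0, ivt_step=0.4)
        for _, row in surf.data.iterrows():
            grid = make_reference_grid(
                global_fit,
                at={"mat": row["mat"], "ivt": row["ivt"]},
                over=("species", "phenophase"),
            )
            ms = marginal_slope(global_fit, "t_std", grid)
            assert row["slope"] == pytest.approx(ms.slope, abs=1e-9)
            assert row["se"] == pytest.approx(ms.se, abs=1e-9)

    def test_species_average_equals_pooled_surface(self, global_fit):
        pooled = sensitivity_surface(global_fit, mat_step=2.0, ivt_step=0.2)
        by_sp = sensitivity_surface(global_fit, mat_step=2.0, ivt_step=0.2, by_species=True)
        avg = by_sp.data.groupby(["mat", "ivt"], as_index=False)["slope"].mean()
        merged = pooled.data.merge(avg, on=["mat", "ivt"], suffixes=("", "_avg"))
        assert np.allclose(merged["slope"], merged["slope_avg"], atol=1e-8)


class TestMapSensitivity:
    def test_record_at_node_equals_node_value(self, global_fit):
        surf = sensitivity_surface(global_fit, mat_step=5.0, ivt_step=0.4)
        node = surf.data.iloc[3]
        rec = pd.DataFrame(
            {
                "id": ["r0"],
                "latitude": [50.0],
                "longitude": [10.0],
                "mat": [node["mat"]],
                "ivt": [node["ivt"]],
            }
        )
        out = map_sensitivity(rec, global_fit)
        assert out.loc[0, "sensitivity"] == pytest.approx(node["slope"], abs=1e-9)
        assert out.loc[0, "se"] == pytest.approx(node["se"], abs=1e-9)

    def test_same_cell_records_share_sensitivity(self, small_covariates, global_fit):
        cells = small_covariates.groupby(["cell_lat", "cell_lon"])
        big = max(cells.groups.values(), key=len)
        sub = small_covariates.loc[big]
        out = map_sensitivity(sub, global_fit)
        assert out["sensitivity"].nunique() == 1

    def test_missing_covariates_rejected(self, global_fit):
        rec = pd.DataFrame({"id": ["a"], "latitude": [0.0], "longitude": [0.0]})
        with pytest.raises(ValueError, match="covariate"):
            map_sensitivity(rec, global_fit)


class TestRanges:
    def test_bilinear_surface_extremes_at_corners(self, global_fit):
        """The pooled slope surface is bilinear in (MAT, IVT); the coarse-grid
        range must equal the corner-evaluation oracle exactly."""
        res = intraspecific_range(global_fit)
        corners = []
        for mat in (-5.0, 15.0):
            for ivt in (0.4, 1.2):
                grid = make_reference_grid(
                    global_fit, at={"mat": mat, "ivt": ivt}, over=("species", "phenophase")
                )
                corners.append(marginal_slope(global_fit, "t_std", grid).slope)
        assert res["range"] == pytest.approx(max(corners) - min(corners), abs=1e-9)
        assert res["max_slope"] == pytest.approx(max(corners), abs=1e-9)
        assert {res["max_at"]["mat"], res["min_at"]["mat"]} <= {-5.0, 15.0}

    def test_range_equals_surface_max_minus_min(self, global_fit):
        res = intraspecific_range(global_fit)
        d = res["surface"].data
        assert res["range"] == pytest.approx(d["slope"].max() - d["slope"].min())
        assert res["surface"].n_nodes == 189

    def test_interspecific_table_and_contrasts(self, global_fit):
        table, summary, pairs = interspecific_range(global_fit)
        assert len(table) == 6
        assert len(pairs) == 15
        assert summary["range"] == pytest.approx(
            table["slope"].max() - table["slope"].min()
        )
        assert (pairs["adjust"] == "tukey").all()

    def test_identical_species_slopes_give_near_zero_range(self, small_grid):
        from phenosense import attach_covariates, fit_global, generate_observations
        from phenosense.synthetic import SensitivityTruth

        truth = SensitivityTruth(
            species_slope_offsets={s: 0.0 for s in SensitivityTruth().species_slope_offsets},
            noise_sd=2.0,
        )
        obs = generate_observations(small_grid, truth, n_per_species_continent=250, seed=31)
        cov = attach_covariates(obs, small_grid)
        fit = fit_global(cov)
        table, summary, _ = interspecific_range(fit)
        # each species slope has its own s.e.; the spread should be noise-level
        assert summary["range"] < 4 * table["se"].max()


class TestPrecipitationAndTrends:
    def test_precipitation_slope_units_and_surface(self, global_fit):
        overall = precipitation_sensitivity(global_fit)
        assert overall.moderators["units"] == "days/mm"
        overall2, surf = precipitation_sensitivity(global_fit, surface=True)
        assert overall2.slope == overall.slope
        assert surf.focal == "p_std"
        assert surf.n_nodes == 1717

    def test_trend_profile_matches_slope_trend(self, global_fit):
        prof = mat_trend_profile(global_fit)
        assert list(prof["ivt"]) == ["overall", "0.4", "0.8", "1.2"]
        for _, row in prof.iloc[1:].iterrows():
            grid = make_reference_grid(
                global_fit,
                at={"ivt": float(row["ivt"])},
                over=("species", "phenophase"),
            )
            tr = slope_trend(global_fit, "t_std", "mat", grid)
            assert row["trend"] == pytest.approx(tr.slope, abs=1e-10)
            assert row["se"] == pytest.approx(tr.se, abs=1e-10)

    def test_trend_profile_finite_difference(self, global_fit):
        """Trend at an IVT level equals the centered finite difference of the
        marginal slope across MAT."""
        h = 1.0
        prof = mat_trend_profile(global_fit, ivt_levels=(0.8,))
        m0 = global_fit.design.covariate_means["mat"]
        slopes = {}
        for sgn in (+1, -1):
            grid = make_reference_grid(
                global_fit, at={"ivt": 0.8, "mat": m0 + sgn * h},
                over=("species", "phenophase"),
            )
            slopes[sgn] = marginal_slope(global_fit, "t_std", grid).slope
        fd = (slopes[+1] - slopes[-1]) / (2 * h)
        assert prof.loc[1, "trend"] == pytest.approx(fd, abs=1e-8)
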