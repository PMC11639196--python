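"""Marginal means/slopes/trends against brute-force and closed-form oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from phenosense.design import ModelSpec
from phenosense.emm import (
    make_reference_grid,
    marginal_mean,
    marginal_slope,
    pairwise_contrasts,
    slope_trend,
)
from phenosense.ols import fit_model


def _tm_dataset(rng, n=120):
    df = pd.DataFrame(
        {
            "g": rng.choice(["a", "b", "c"], n),
            "t": rng.normal(size=n),
            "m": rng.normal(2.0, 1.0, n),
        }
    )
    df["y"] = 1.0 + 2.0 * df["t"] - 0.7 * df["t"] * df["m"] + rng.normal(0, 0.3, n)
    return df


def brute_force_mean(fit, at, over):
    """Average model predictions over explicit grid-point rows."""
    info = fit.design
    levels = {f: info.factor_levels[f] for f in over}
    rows = []
    for combo in itertools.product(*levels.values()):
        row = {c: info.covariate_means[c] for c in info.covariate_names}
        row.update(at)
        row.update(dict(zip(levels, combo)))
        rows.append(row)
    frame = pd.DataFrame(rows)
    return float(fit.predict(frame).mean())


class TestMarginalMean:
    def test_intercept_only_closed_form(self, rng):
        y = rng.normal(3.0, 1.5, 50)
        fit = fit_model(pd.DataFrame({"y": y}), ModelSpec(response="y", products=()))
        grid = make_reference_grid(fit)
        est = marginal_mean(fit, grid)
        assert est.estimate == pytest.approx(y.mean())
        assert est.se == pytest.approx(np.sqrt(fit.scale / len(y)))

    def test_equals_average_of_predictions(self, rng):
        df = _tm_dataset(rng)
        fit = fit_model(df, ModelSpec(response="y", products=(("t", "m", "g"),)))
        grid = make_reference_grid(fit, at={"m": 1.5}, over=("g",))
        assert marginal_mean(fit, grid).estimate == pytest.approx(
            brute_force_mean(fit, {"m": 1.5}, ("g",)), abs=1e-8
        )

    def test_grid_shapes(self, rng):
        df = _tm_dataset(rng)
        fit = fit_model(df, ModelSpec(response="y", products=(("t", "g"),)))
        grid = make_reference_grid(fit, over=("g",))
        assert len(grid.points) == 3
        assert np.allclose(grid.weights, 1 / 3)
        single = make_reference_grid(fit, at={"g": "a"})
        assert len(single.points) == 1

    def test_unknown_variable_is_error(self, rng):
        df = _tm_dataset(rng)
        fit = fit_model(df, ModelSpec(response="y", products=(("t", "g"),)))
        with pytest.raises(ValueError, match="unknown model variable"):
            make_reference_grid(fit, at={"MAT": 0.8}, over=("g",))
        with pytest.raises(ValueError, match="fixed .* or averaged"):
            make_reference_grid(fit)  # factor g unassigned

    def test_out_of_range_moderator_warns(self, rng):
        df = _tm_dataset(rng)
        fit = fit_model(df, ModelSpec(response="y", products=(("t", "m", "g"),)))
        with pytest.warns(UserWarning, match="outside the observed range"):
            make_reference_grid(fit, at={"m": 50.0}, over=("g",))


class TestMarginalSlope:
    def test_no_interaction_slope_is_coefficient(self, rng):
        df = _tm_dataset(rng)
        fit = fit_model(df, ModelSpec(response="y", products=(("t",), ("m",), ("g",))))
        j = fit.column_names.index("t")
        for m in (-1.0, 0.0, 2.5):
            grid = make_reference_grid(fit, at={"m": m}, over=("g",))
            assert marginal_slope(fit, "t", grid).slope == pytest.approx(fit.params[j])

    def test_interaction_closed_form(self, rng):
        df = _tm_dataset(rng)
        fit = fit_model(df, ModelSpec(response="y", products=(("t", "m"),)))
        bt = fit.params[fit.column_names.index("t")]
        btm = fit.params[fit.column_names.index("t:m")]
        grid = make_reference_grid(fit, at={"m": 1.7})
        assert marginal_slope(fit, "t", grid).slope == pytest.approx(bt + 1.7 * btm)

    def test_matches_finite_difference_of_means(self, global_fit):
        """On the full global model the analytic slope equals the centered
        finite difference of marginal means (exact for a linear model)."""
        h = 0.5
        for mat, ivt in [(-5.0, 0.4), (5.0, 0.8), (15.0, 1.2)]:
            at = {"mat": mat, "ivt": ivt}
            over = ("species", "phenophase")
            grid = make_reference_grid(global_fit, at=at, over=over)
            slope = marginal_slope(global_fit, "t_std", grid).slope
            mm = {}
            for sgn in (+1, -1):
                t0 = global_fit.design.covariate_means["t_std"] + sgn * h
                g = make_reference_grid(global_fit, at={**at, "t_std": t0}, over=over)
                mm[sgn] = marginal_mean(global_fit, g).estimate
            fd = (mm[+1] - mm[-1]) / (2 * h)
            assert slope == pytest.approx(fd, abs=1e-8)

    def test_focal_factor_is_error(self, global_fit):
        grid = make_reference_grid(global_fit, over=("species", "phenophase"))
        with pytest.raises(ValueError, match="factor"):
            marginal_slope(global_fit, "species", grid)


class TestSlopeTrend:
    def test_interaction_model_trend_is_coefficient(self, rng):
        df = _tm_dataset(rng)
        fit = fit_model(df, ModelSpec(response="y", products=(("t", "m"),)))
        btm = fit.params[fit.column_names.index("t:m")]
        grid = make_reference_grid(fit)
        assert slope_trend(fit, "t", "m", grid).slope == pytest.approx(btm)

    def test_absent_interaction_is_exact_zero(self, rng):
        df = _tm_dataset(rng)
        fit = fit_model(df, ModelSpec(response="y", products=(("t",), ("m",))))
        grid = make_reference_grid(fit)
        tr = slope_trend(fit, "t", "m", grid)
        assert tr.slope == 0.0 and tr.se == 0.0

    def test_matches_finite_difference_of_slopes(self, global_fit):
        h = 0.25
        at = {"ivt": 0.9}
        over = ("species", "phenophase")
        grid = make_reference_grid(global_fit, at=at, over=over)
        trend = slope_trend(global_fit, "t_std", "mat", grid).slope
        m0 = global_fit.design.covariate_means["mat"]
        slopes = {}
        for sgn in (+1, -1):
            g = make_reference_grid(global_fit, at={**at, "mat": m0 + sgn * h}, over=over)
            slopes[sgn] = marginal_slope(global_fit, "t_std", g).slope
        assert trend == pytest.approx((slopes[+1] - slopes[-1]) / (2 * h), abs=1e-8)


class TestReferenceLevelInvariance:
    def test_marginal_quantities_invariant_to_coding(self, small_covariates):
        from phenosense.design import global_model_spec

        base = fit_model(small_covariates, global_model_spec())
        spec = global_model_spec()
        spec.reference = {"species": "Lythrum salicaria", "phenophase": "fruiting"}
        alt = fit_model(small_covariates, spec)
        for mat, ivt in [(0.0, 0.6), (10.0, 1.0)]:
            at = {"mat": mat, "ivt": ivt}
            g1 = make_reference_grid(base, at=at, over=("species", "phenophase"))
            g2 = make_reference_grid(alt, at=at, over=("species", "phenophase"))
            assert marginal_slope(base, "t_std", g1).slope == pytest.approx(
                marginal_slope(alt, "t_std", g2).slope, abs=1e-8
            )
            assert marginal_mean(base, g1).estimate == pytest.approx(
                marginal_mean(alt, g2).estimate, abs=1e-8
            )


class TestPairwiseContrasts:
    def _random_instance(self, rng, k):
        A = rng.normal(size=(k, k + 2))
        cov = A @ A.T / 10
        est = rng.normal(size=k)
        return est, cov

    def test_k2_tukey_equals_t_test(self, rng):
        est, cov = self._random_instance(rng, 2)
        tuk = pairwise_contrasts(["a", "b"], est, cov, df=40, adjust="tukey")
        un = pairwise_contrasts(["a", "b"], est, cov, df=40, adjust="none")
        assert tuk.loc[0, "p"] == pytest.approx(un.loc[0, "p"], rel=1e-5)

    def test_identical_estimates_give_p_one(self):
        cov = np.eye(2) * 0.5
        out = pairwise_contrasts(["a", "b"], [1.0, 1.0], cov, df=10)
        assert out.loc[0, "estimate"] == 0.0
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_adjusted_p_never_smaller(self, rng):
        est, cov = self._random_instance(rng, 5)
        tuk = pairwise_contrasts(list("abcde"), est, cov, df=30, adjust="tukey")
        un = pairwise_contrasts(list("abcde"), est, cov, df=30, adjust="none")
        assert (tuk["p"] >= un["p"] - 1e-12).all()
        assert len(tuk) == 10

    def test_non_psd_covariance_is_error(self):
        cov = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
        with pytest.raises(ValueError, match="positive semidefinite"):
            pairwise_contrasts(["a", "b"], [0.0, 1.0], cov, df=10)

    def test_tukey_matches_studentized_range_tail(self, rng):
        est, cov = self._random_instance(rng, 4)
        out = pairwise_contrasts(list("abcd"), est, cov, df=25)
        row = out.iloc[0]
        q = abs(row["t"]) * np.sqrt(2)
        assert row["p"] == pytest.approx(scipy.stats.studentized_range.sf(q, 4, 25))
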