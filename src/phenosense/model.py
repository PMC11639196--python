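"""Scikit-learn style estimator for the global sensitivity model.

:class:`PhenologySensitivityModel` wraps design construction, OLS fitting
and the marginal-inference post hoc analyses behind a fit/predict surface,
so the whole procedure composes with sklearn pipelines (e.g. after
:class:`~phenosense.covariates.ClimateCovariateExtractor`).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from . import analysis
from .design import ModelSpec, global_model_spec
from .emm import make_reference_grid, marginal_slope
from .ols import FittedModel, fit_model, residual_kurtosis


class PhenologySensitivityModel(BaseEstimator, RegressorMixin):
    """Global interaction model of phenology day of year.

    Fits ``doy ~ (t_std x mat x ivt x species) + (p_std x mat x ivt x
    species) + (phenophase x mat x ivt x species)`` by OLS (all marginal
    terms included) and exposes the temperature-sensitivity post hoc
    analyses as methods.

    Parameters
    ----------
    spec : ModelSpec, optional
        Alternative model specification; defaults to the global model.
    reference : dict, optional
        Reference level per factor (defaults alphabetical; marginal
        estimates are invariant to this choice).

    Attributes
    ----------
    result_ : FittedModel
        Coefficients, covariance and design structure.
    coef_ : ndarray
        Fitted coefficient vector.
    aic_, r_squared_adj_, df_resid_, n_obs_ : float / int
        Fit statistics.
    """

    def __init__(self, spec: ModelSpec | None = None, reference: dict | None = None):
        self.spec = spec
        self.reference = reference

    def _resolved_spec(self) -> ModelSpec:
        spec = self.spec if self.spec is not None else global_model_spec()
        if self.reference:
            spec = ModelSpec(
                response=spec.response,
                products=spec.products,
                factor_levels=spec.factor_levels,
                reference=dict(self.reference),
            )
        return spec

    def fit(self, X: pd.DataFrame, y=None) -> "PhenologySensitivityModel":
        """Fit on a curated observation table with covariates attached."""
        self.result_: FittedModel = fit_model(X, self._resolved_spec())
        self.coef_ = self.result_.params
        self.aic_ = self.result_.aic
        self.r_squared_adj_ = self.result_.r_squared_adj
        self.df_resid_ = self.result_.df_resid
        self.n_obs_ = self.result_.nobs
        return self

    def _check_fitted(self) -> FittedModel:
        if not hasattr(self, "result_"):
            raise ValueError("model is not fitted")
        return self.result_

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self._check_fitted().predict(X)

    def coef_table(self) -> pd.DataFrame:
        return self._check_fitted().coef_table()

    def residual_kurtosis(self) -> float:
        return residual_kurtosis(self._check_fitted())

    # -- post hoc analyses -------------------------------------------------
    def baseline_sensitivity(self):
        """Overall temperature sensitivity (days/degC) at the mean climate."""
        model = self._check_fitted()
        grid = make_reference_grid(model, over=tuple(model.design.factor_levels))
        return marginal_slope(model, "t_std", grid)

    def sensitivity_surface(self, **kwargs) -> analysis.SensitivitySurface:
        return analysis.sensitivity_surface(self._check_fitted(), **kwargs)

    def map_sensitivity(self, records: pd.DataFrame) -> pd.DataFrame:
        return analysis.map_sensitivity(records, self._check_fitted())

    def intraspecific_range(self, **kwargs) -> dict:
        return analysis.intraspecific_range(self._check_fitted(), **kwargs)

    def interspecific_range(self, **kwargs):
        return analysis.interspecific_range(self._check_fitted(), **kwargs)

    def precipitation_sensitivity(self, **kwargs):
        return analysis.precipitation_sensitivity(self._check_fitted(), **kwargs)

    def mat_trend_profile(self, **kwargs) -> pd.DataFrame:
        return analysis.mat_trend_profile(self._check_fitted(), **kwargs)
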