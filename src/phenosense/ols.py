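"""Ordinary least squares fitting, fit statistics and AIC model selection.

Fitting is delegated to statsmodels OLS on the explicitly built design
matrix; the fitted object keeps the design structure so marginal inference
can form exact coefficient contrasts. AIC uses the full Gaussian
log-likelihood convention,

    AIC = n ln(RSS/n) + n ln(2 pi) + n + 2 k,

with k the number of regression coefficients, so differences are comparable
with common statistical packages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .design import (
    DesignInfo,
    ModelSpec,
    aim1_climate_spec,
    aim1_phenology_spec,
    build_design_matrix,
    global_model_spec,
)


@dataclass
class FittedModel:
    """An OLS fit with its design structure and sampling covariance."""

    params: np.ndarray
    cov_params: np.ndarray
    df_resid: int
    nobs: int
    aic: float
    r_squared_adj: float
    resid: np.ndarray
    scale: float  # residual variance estimate s^2
    design: DesignInfo

    @property
    def column_names(self) -> list[str]:
        return self.design.column_names

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        return self.design.matrix(data) @ self.params

    def coef_table(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov_params))
        t = self.params / se
        p = 2 * scipy.stats.t.sf(np.abs(t), self.df_resid)
        return pd.DataFrame(
            {"term": self.column_names, "estimate": self.params, "se": se, "t": t, "p": p}
        )

    def fit_stats(self) -> dict:
        return {
            "n": int(self.nobs),
            "k": int(len(self.params)),
            "df_resid": int(self.df_resid),
            "aic": float(self.aic),
            "r_squared_adj": float(self.r_squared_adj),
            "residual_kurtosis": residual_kurtosis(self),
        }


def fit_ols(X: np.ndarray, y: np.ndarray, design: DesignInfo) -> FittedModel:
    """Fit by OLS; error (upstream) if the design is rank deficient."""
    y = np.asarray(y, dtype=float)
    if X.shape[0] <= X.shape[1]:
        raise ValueError(
            f"need more observations ({X.shape[0]}) than parameters ({X.shape[1]})"
        )
    res = sm.OLS(y, X).fit()
    return FittedModel(
        params=res.params,
        cov_params=np.asarray(res.cov_params()),
        df_resid=int(res.df_resid),
        nobs=int(res.nobs),
        aic=float(res.aic),
        r_squared_adj=float(res.rsquared_adj),
        resid=np.asarray(res.resid),
        scale=float(res.scale),
        design=design,
    )


def fit_model(data: pd.DataFrame, spec: ModelSpec) -> FittedModel:
    """Build the design for ``spec`` on ``data`` and fit by OLS."""
    needed = [spec.response] + spec.variables()
    frame = data.loc[:, needed]
    if frame.isna().any().any():
        raise ValueError("model variables contain missing values; curate first")
    X, info = build_design_matrix(frame, spec)
    return fit_ols(X, frame[spec.response].to_numpy(dtype=float), info)


def fit_aim1_climate(data: pd.DataFrame) -> dict[str, FittedModel]:
    """Spatial models of the climate normals: MAT/IVT ~ continent + latitude."""
    return {
        "mat": fit_model(data, aim1_climate_spec("mat")),
        "ivt": fit_model(data, aim1_climate_spec("ivt")),
    }


def fit_aim1_phenology(data: pd.DataFrame) -> FittedModel:
    """Spatial phenology model: doy ~ phenophase x (continent+latitude+species)."""
    return fit_model(data, aim1_phenology_spec())


def fit_global(data: pd.DataFrame) -> FittedModel:
    """The global temperature-sensitivity interaction model."""
    return fit_model(data, global_model_spec())


def residual_kurtosis(model: FittedModel) -> float:
    """Excess kurtosis of the residuals (0 for Gaussian, >0 leptokurtic)."""
    r = model.resid
    if np.allclose(r, r[0]):
        raise ValueError("residuals are constant; kurtosis is undefined")
    return float(scipy.stats.kurtosis(r, fisher=True, bias=False))


def aic_select(
    data: pd.DataFrame, candidates: dict[str, ModelSpec]
) -> tuple[pd.DataFrame, FittedModel]:
    """Fit candidate specs on identical rows and rank by AIC (ascending).

    Returns the ranking table (with delta AIC relative to the best) and the
    best fitted model. All candidates must be estimable on the same rows;
    missing values anywhere in the union of their variables are an error so
    no candidate silently fits a different subset.
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidate specifications")
    needed: list[str] = []
    for spec in candidates.values():
        for v in [spec.response] + spec.variables():
            if v not in needed:
                needed.append(v)
    frame = data.loc[:, needed]
    if frame.isna().any().any():
        bad = frame.columns[frame.isna().any()].tolist()
        raise ValueError(
            f"missing values in {bad}: candidates would fit on differing row subsets"
        )

    fits = {name: fit_model(frame, spec) for name, spec in candidates.items()}
    table = pd.DataFrame(
        {
            "model": list(fits),
            "k": [len(f.params) for f in fits.values()],
            "aic": [f.aic for f in fits.values()],
            "r_squared_adj": [f.r_squared_adj for f in fits.values()],
        }
    ).sort_values("aic", kind="stable", ignore_index=True)
    table["delta_aic"] = table["aic"] - table["aic"].iloc[0]
    return table, fits[table["model"].iloc[0]]
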