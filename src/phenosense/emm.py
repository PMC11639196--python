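"""Estimated marginal means and simple slopes for fitted linear models.

A *reference grid* fixes some model variables ("at"), averages over the
levels of others ("over", equal weights by default) and holds every
remaining covariate at its sample mean. Marginal quantities are linear
functionals c'beta of the coefficients:

* marginal mean -- c is the weighted average of design rows over the grid;
* marginal (simple) slope -- c is the weighted average of design-row
  derivatives with respect to a focal covariate, which this package
  computes exactly from the term structure (no numeric differentiation);
* slope trend -- second cross-derivative, e.g. the change of temperature
  sensitivity per degree MAT.

Standard errors are delta-method, se = sqrt(c' Sigma c) with Sigma the
coefficient covariance; tests are two-sided t at the model's residual
degrees of freedom. Pairwise contrasts support Tukey HSD adjustment via the
studentized range distribution.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .ols import FittedModel


@dataclass
class ReferenceGrid:
    """Prediction points with averaging weights over the "over" set."""

    points: list[dict]
    weights: np.ndarray
    at: dict = field(default_factory=dict)
    over: tuple[str, ...] = ()


@dataclass
class MarginalEstimate:
    estimate: float
    se: float
    df: int
    t: float
    p: float
    at: dict = field(default_factory=dict)


@dataclass
class MarginalSlope:
    """A sensitivity estimate: slope of a focal covariate at fixed moderators."""

    focal: str
    moderators: dict
    slope: float
    se: float
    df: int
    t: float
    p: float


def make_reference_grid(
    model: FittedModel,
    at: dict | None = None,
    over: tuple[str, ...] | str = (),
    weights: str = "equal",
) -> ReferenceGrid:
    """Build a reference grid for a fitted model.

    Every factor must appear in ``at`` (fixed to one level) or ``over``
    (averaged across levels); unfixed covariates are set to their sample
    means. Fixing a covariate outside its observed range is allowed with a
    warning (sensitivity surfaces deliberately extend past the data).
    """
    at = dict(at or {})
    over = (over,) if isinstance(over, str) else tuple(over)
    info = model.design

    known = set(info.factor_levels) | set(info.covariate_names)
    for v in list(at) + list(over):
        if v not in known:
            raise ValueError(f"unknown model variable {v!r}")
    for v in over:
        if v not in info.factor_levels:
            raise ValueError(f"'over' variables must be factors, got covariate {v!r}")
    for f in info.factor_levels:
        if f not in at and f not in over:
            raise ValueError(
                f"factor {f!r} must be fixed ('at') or averaged ('over')"
            )

    base: dict = {}
    for c, mean in info.covariate_means.items():
        base[c] = float(at[c]) if c in at else mean
        if c in at:
            lo, hi = info.covariate_ranges[c]
            if not lo <= base[c] <= hi:
                warnings.warn(
                    f"{c}={base[c]} lies outside the observed range [{lo:.4g}, {hi:.4g}]",
                    stacklevel=2,
                )
    for f in info.factor_levels:
        if f in at:
            if str(at[f]) not in info.factor_levels[f]:
                raise ValueError(f"{at[f]!r} is not a level of factor {f!r}")
            base[f] = str(at[f])

    combos = list(itertools.product(*[info.factor_levels[f] for f in over]))
    points = []
    for combo in combos:
        a = dict(base)
        a.update(dict(zip(over, combo)))
        points.append(a)
    if weights == "equal":
        w = np.full(len(points), 1.0 / len(points))
    elif weights == "proportional":
        raise NotImplementedError("proportional weights: use weights_from(data)")
    else:
        raise ValueError("weights must be 'equal'")
    return ReferenceGrid(points=points, weights=w, at=at, over=over)


def mean_contrast(model: FittedModel, grid: ReferenceGrid) -> np.ndarray:
    """Coefficient contrast whose value is the estimated marginal mean."""
    rows = np.array([model.design.row(p) for p in grid.points])
    return grid.weights @ rows


def slope_contrast(
    model: FittedModel, focal: tuple[str, ...] | str, grid: ReferenceGrid
) -> np.ndarray:
    """Contrast for the (cross-)derivative w.r.t. the focal covariate(s)."""
    focal = (focal,) if isinstance(focal, str) else tuple(focal)
    for f in focal:
        if f in model.design.factor_levels:
            raise ValueError(f"focal variable {f!r} is a factor, not a covariate")
    rows = np.array([model.design.derivative_row(p, focal) for p in grid.points])
    return grid.weights @ rows


def _infer(model: FittedModel, c: np.ndarray) -> tuple[float, float, float, float]:
    est = float(c @ model.params)
    se = float(np.sqrt(c @ model.cov_params @ c))
    t = est / se if se > 0 else np.inf * np.sign(est) if est else 0.0
    p = float(2 * scipy.stats.t.sf(abs(t), model.df_resid)) if np.isfinite(t) else 0.0
    return est, se, t, p


def marginal_mean(model: FittedModel, grid: ReferenceGrid) -> MarginalEstimate:
    """Estimated marginal mean of the response over a reference grid."""
    est, se, t, p = _infer(model, mean_contrast(model, grid))
    return MarginalEstimate(est, se, model.df_resid, t, p, at=dict(grid.at))


def marginal_slope(
    model: FittedModel, focal: str, grid: ReferenceGrid
) -> MarginalSlope:
    """Simple slope of a focal covariate at the grid's moderator settings."""
    est, se, t, p = _infer(model, slope_contrast(model, focal, grid))
    return MarginalSlope(
        focal=focal, moderators=dict(grid.at), slope=est, se=se,
        df=model.df_resid, t=t, p=p,
    )


def slope_trend(
    model: FittedModel, focal: str, wrt: str, grid: ReferenceGrid
) -> MarginalSlope:
    """Second-order trend: change of the focal slope per unit of ``wrt``."""
    est, se, t, p = _infer(model, slope_contrast(model, (focal, wrt), grid))
    return MarginalSlope(
        focal=f"d({focal})/d({wrt})", moderators=dict(grid.at), slope=est, se=se,
        df=model.df_resid, t=t, p=p,
    )


def pairwise_contrasts(
    labels,
    estimates: np.ndarray,
    cov: np.ndarray,
    df: int,
    adjust: str = "tukey",
) -> pd.DataFrame:
    """All pairwise differences with optional Tukey HSD adjustment.

    Tukey p-values come from the studentized range distribution with k
    groups at the model's residual df (q = |t|*sqrt(2)); with ``adjust
    ="none"`` ordinary two-sided t p-values are reported.
    """
    estimates = np.asarray(estimates, dtype=float)
    cov = np.asarray(cov, dtype=float)
    k = len(estimates)
    if k < 2:
        raise ValueError("need at least two estimates to contrast")
    if cov.shape != (k, k):
        raise ValueError("covariance shape does not match the estimates")
    eig = np.linalg.eigvalsh((cov + cov.T) / 2)
    if eig.min() < -1e-8 * max(1.0, eig.max()):
        raise ValueError("covariance of the estimates is not positive semidefinite")
    if adjust not in ("tukey", "none"):
        raise ValueError("adjust must be 'tukey' or 'none'")

    rows = []
    for i, j in itertools.combinations(range(k), 2):
        diff = estimates[i] - estimates[j]
        var = cov[i, i] + cov[j, j] - 2 * cov[i, j]
        se = float(np.sqrt(max(var, 0.0)))
        if se == 0.0:
            t = 0.0 if diff == 0 else np.inf
        else:
            t = diff / se
        if not np.isfinite(t):
            p = 0.0
        elif adjust == "tukey":
            p = float(scipy.stats.studentized_range.sf(abs(t) * np.sqrt(2), k, df))
        else:
            p = float(2 * scipy.stats.t.sf(abs(t), df))
        rows.append(
            {
                "contrast": f"{labels[i]} - {labels[j]}",
                "estimate": diff,
                "se": se,
                "t": t,
                "p": min(p, 1.0),
                "df": df,
                "adjust": adjust,
            }
        )
    return pd.DataFrame(rows)
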