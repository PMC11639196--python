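"""Sensitivity surfaces, geographic projection and variation summaries.

Temperature sensitivity is the marginal slope of standardized temperature on
day of year (days/degC), a function of the moderating climate normals MAT
and IVT. This module evaluates that slope:

* on a regular MAT x IVT grid (the "sensitivity surface"; fine grid
  0.2 degC x 0.05 s.d. for mapping, coarse 1 degC x 0.1 s.d. for range
  summaries), averaged over species and phenophase with precipitation
  controlled, or per species;
* at each observation's exact MAT/IVT (geographic projection, one value per
  record, joinable on coordinates for mapping);
* summarized as intraspecific range (max minus min over the coarse grid)
  and interspecific range (max minus min of per-species mean slopes);
* for precipitation (days/mm) via the same machinery;
* as the conditional effect of MAT on sensitivity at chosen IVT levels.

All quantities are exact linear functionals of the fitted coefficients with
delta-method standard errors.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .emm import (
    MarginalSlope,
    make_reference_grid,
    marginal_slope,
    pairwise_contrasts,
    slope_contrast,
    slope_trend,
)
from .ols import FittedModel

#: Fine grid used for surfaces and maps (0.2 degC x 0.05 s.d.).
FINE_GRID = {"mat_range": (-5.0, 15.0), "mat_step": 0.2, "ivt_range": (0.4, 1.2), "ivt_step": 0.05}
#: Coarse grid used for the intraspecific range summary (1 degC x 0.1 s.d.).
COARSE_GRID = {"mat_range": (-5.0, 15.0), "mat_step": 1.0, "ivt_range": (0.4, 1.2), "ivt_step": 0.1}


def model_hash(model: FittedModel) -> str:
    h = hashlib.sha256()
    h.update(np.asarray(model.params).tobytes())
    h.update(",".join(model.column_names).encode())
    return h.hexdigest()[:16]


def _axis(rng: tuple[float, float], step: float, name: str) -> np.ndarray:
    lo, hi = rng
    if step <= 0 or hi <= lo:
        raise ValueError(f"invalid {name} grid: range {rng}, step {step}")
    n = (hi - lo) / step
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"{name} step {step} does not divide the range {rng}")
    # round away accumulated float error so node coordinates are exact grid values
    return np.round(lo + step * np.arange(int(round(n)) + 1), 9)


@dataclass
class SensitivitySurface:
    """Marginal slopes on a regular MAT x IVT grid (optionally per species)."""

    data: pd.DataFrame  # columns: mat, ivt, [species], slope, se, t, p, df
    mat_axis: np.ndarray
    ivt_axis: np.ndarray
    focal: str
    species: tuple[str, ...] | None = None
    provenance: str = ""

    @property
    def n_nodes(self) -> int:
        return len(self.data)

    def pivot(self, species: str | None = None) -> pd.DataFrame:
        """Slope as a MAT-by-IVT table (rows MAT, columns IVT)."""
        d = self.data
        if species is not None:
            d = d[d["species"] == species]
        return d.pivot(index="mat", columns="ivt", values="slope")

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def _factor_weight(model, col, at: dict, over) -> float:
    """Averaging weight of a column's factor-level part on a reference grid."""
    w = 1.0
    for f, lv in col.levels:
        if f in at:
            if str(at[f]) != lv:
                return 0.0
        elif f in over:
            w /= len(model.design.factor_levels[f])
        else:
            raise ValueError(f"factor {f!r} neither fixed nor averaged")
    return w


def _slope_contrast_matrix(
    model: FittedModel,
    focal: str,
    moderators: dict[str, np.ndarray],
    at_factors: dict | None = None,
) -> np.ndarray:
    """Contrast rows for the focal slope at many moderator settings at once.

    ``moderators`` maps covariate names to aligned value arrays; any other
    covariate appearing in a focal column is fixed at its sample mean.
    Factors are averaged equally unless fixed in ``at_factors``.
    """
    info = model.design
    if focal in info.factor_levels:
        raise ValueError(f"focal variable {focal!r} is a factor, not a covariate")
    at = dict(at_factors or {})
    over = [f for f in info.factor_levels if f not in at]
    n = len(next(iter(moderators.values()))) if moderators else 1
    C = np.zeros((n, len(info.columns)))
    for j, col in enumerate(info.columns):
        if focal not in col.covariates:
            continue
        w = _factor_weight(model, col, at, over)
        if w == 0.0:
            continue
        vec = np.full(n, w)
        for c in col.covariates:
            if c == focal:
                continue
            vec = vec * (moderators[c] if c in moderators else info.covariate_means[c])
        C[:, j] = vec
    return C


def _contrast_inference(model: FittedModel, C: np.ndarray) -> pd.DataFrame:
    est = C @ model.params
    var = np.einsum("ij,jk,ik->i", C, model.cov_params, C)
    se = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, est / se, 0.0)
    p = 2 * scipy.stats.t.sf(np.abs(t), model.df_resid)
    return pd.DataFrame({"slope": est, "se": se, "t": t, "p": p, "df": model.df_resid})


def sensitivity_surface(
    model: FittedModel,
    mat_range: tuple[float, float] = FINE_GRID["mat_range"],
    mat_step: float = FINE_GRID["mat_step"],
    ivt_range: tuple[float, float] = FINE_GRID["ivt_range"],
    ivt_step: float = FINE_GRID["ivt_step"],
    by_species: bool = False,
    focal: str = "t_std",
) -> SensitivitySurface:
    """Marginal focal slope at every MAT x IVT node.

    Averaged equally over species and phenophase (or per species when
    ``by_species``), with every other covariate -- notably standardized
    precipitation -- held at its sample mean.
    """
    mat_axis = _axis(mat_range, mat_step, "MAT")
    ivt_axis = _axis(ivt_range, ivt_step, "IVT")
    mm, vv = np.meshgrid(mat_axis, ivt_axis, indexing="ij")
    mods = {"mat": mm.ravel(), "ivt": vv.ravel()}

    species_levels = model.design.factor_levels.get("species")
    frames = []
    if by_species:
        if species_levels is None:
            raise ValueError("model has no species factor")
        for sp in species_levels:
            C = _slope_contrast_matrix(model, focal, mods, at_factors={"species": sp})
            d = _contrast_inference(model, C)
            d.insert(0, "ivt", mods["ivt"])
            d.insert(0, "mat", mods["mat"])
            d.insert(0, "species", sp)
            frames.append(d)
        data = pd.concat(frames, ignore_index=True)
    else:
        C = _slope_contrast_matrix(model, focal, mods)
        data = _contrast_inference(model, C)
        data.insert(0, "ivt", mods["ivt"])
        data.insert(0, "mat", mods["mat"])
    return SensitivitySurface(
        data=data,
        mat_axis=mat_axis,
        ivt_axis=ivt_axis,
        focal=focal,
        species=tuple(species_levels) if by_species else None,
        provenance=model_hash(model),
    )


def map_sensitivity(
    records: pd.DataFrame, model: FittedModel, focal: str = "t_std"
) -> pd.DataFrame:
    """Project the sensitivity estimate onto each observation.

    The slope is evaluated at the record's exact MAT and IVT (not a nearest
    grid node), so two records sharing a climate cell share a sensitivity.
    Output is keyed by record id with coordinates for mapping.
    """
    for c in ("mat", "ivt"):
        if c not in records.columns:
            raise ValueError(f"records lack the {c!r} covariate; run covariate extraction")
        if records[c].isna().any():
            raise ValueError(f"records have missing {c!r} values")
    pairs = records[["mat", "ivt"]].astype(float)
    uniq, inverse = np.unique(pairs.to_numpy(), axis=0, return_inverse=True)
    C = _slope_contrast_matrix(model, focal, {"mat": uniq[:, 0], "ivt": uniq[:, 1]})
    d = _contrast_inference(model, C)
    out = records.loc[:, ["id", "latitude", "longitude", "mat", "ivt"]].reset_index(drop=True)
    out["sensitivity"] = d["slope"].values[inverse]
    out["se"] = d["se"].values[inverse]
    return out


def intraspecific_range(
    model: FittedModel,
    mat_range: tuple[float, float] = COARSE_GRID["mat_range"],
    mat_step: float = COARSE_GRID["mat_step"],
    ivt_range: tuple[float, float] = COARSE_GRID["ivt_range"],
    ivt_step: float = COARSE_GRID["ivt_step"],
) -> dict:
    """Spread of temperature sensitivity across the climatic study area.

    Evaluates the species-averaged surface on the coarse summary grid and
    reports the extreme slopes, where they occur, and their difference.
    """
    surf = sensitivity_surface(
        model, mat_range, mat_step, ivt_range, ivt_step, by_species=False
    )
    d = surf.data
    imax = d["slope"].idxmax()
    imin = d["slope"].idxmin()
    return {
        "max_slope": float(d.loc[imax, "slope"]),
        "max_se": float(d.loc[imax, "se"]),
        "max_at": {"mat": float(d.loc[imax, "mat"]), "ivt": float(d.loc[imax, "ivt"])},
        "min_slope": float(d.loc[imin, "slope"]),
        "min_se": float(d.loc[imin, "se"]),
        "min_at": {"mat": float(d.loc[imin, "mat"]), "ivt": float(d.loc[imin, "ivt"])},
        "range": float(d.loc[imax, "slope"] - d.loc[imin, "slope"]),
        "surface": surf,
    }


def interspecific_range(
    model: FittedModel, adjust: str = "tukey"
) -> tuple[pd.DataFrame, dict, pd.DataFrame]:
    """Per-species mean temperature sensitivity and its spread.

    Each species' slope is averaged over phenophase with MAT, IVT and
    standardized precipitation at their sample means. Returns the species
    table, a range summary, and Tukey-adjusted pairwise contrasts.
    """
    info = model.design
    if "species" not in info.factor_levels:
        raise ValueError("model has no species factor")
    over = tuple(f for f in info.factor_levels if f != "species")
    contrasts = []
    for sp in info.factor_levels["species"]:
        grid = make_reference_grid(model, at={"species": sp}, over=over)
        contrasts.append(slope_contrast(model, "t_std", grid))
    C = np.array(contrasts)
    d = _contrast_inference(model, C)
    table = pd.DataFrame({"species": info.factor_levels["species"]}).join(d)
    cov = C @ model.cov_params @ C.T
    pairs = pairwise_contrasts(
        list(table["species"]), d["slope"].values, cov, model.df_resid, adjust=adjust
    )
    imax, imin = d["slope"].idxmax(), d["slope"].idxmin()
    summary = {
        "max_species": table.loc[imax, "species"],
        "max_slope": float(d.loc[imax, "slope"]),
        "min_species": table.loc[imin, "species"],
        "min_slope": float(d.loc[imin, "slope"]),
        "range": float(d.loc[imax, "slope"] - d.loc[imin, "slope"]),
    }
    return table, summary, pairs


def precipitation_sensitivity(
    model: FittedModel, surface: bool = False
) -> MarginalSlope | tuple[MarginalSlope, SensitivitySurface]:
    """Average marginal slope of standardized precipitation (days/mm).

    Averaged over species and phenophase with MAT and IVT at sample means;
    optionally also the full precipitation-sensitivity surface.
    """
    info = model.design
    grid = make_reference_grid(model, over=tuple(info.factor_levels))
    overall = marginal_slope(model, "p_std", grid)
    overall.moderators["units"] = "days/mm"
    if not surface:
        return overall
    return overall, sensitivity_surface(model, focal="p_std")


def mat_trend_profile(
    model: FittedModel, ivt_levels: tuple[float, ...] = (0.4, 0.8, 1.2)
) -> pd.DataFrame:
    """Conditional effect of MAT on temperature sensitivity by IVT level.

    The trend (delta sensitivity per degC MAT) is the second cross
    derivative of the marginal mean in t_std and mat; the first row
    ("overall") evaluates it at the sample-mean IVT.
    """
    info = model.design
    over = tuple(info.factor_levels)
    rows = []
    levels = [("overall", None)] + [(f"{v:g}", float(v)) for v in ivt_levels]
    for label, v in levels:
        at = {} if v is None else {"ivt": v}
        grid = make_reference_grid(model, at=at, over=over)
        tr = slope_trend(model, "t_std", "mat", grid)
        rows.append(
            {
                "ivt": label,
                "trend": tr.slope,
                "se": tr.se,
                "t": tr.t,
                "p": tr.p,
                "df": tr.df,
            }
        )
    return pd.DataFrame(rows)
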