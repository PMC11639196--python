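"""Per-record climate covariates from a gridded monthly climate.

For each observation the pipeline derives:

* ``t_seasonal`` / ``p_seasonal`` -- mean temperature (degC) and
  precipitation (mm/month) over the species' seasonal window (Jan-Mar for
  spring bloomers, Mar-May for summer bloomers) of the observation year;
* ``t_std`` / ``p_std`` -- the same values mean-centred within a
  standardization group (species by default), the covariates whose slopes
  are the temperature and precipitation sensitivities;
* ``mat`` / ``ivt`` -- 1901-2021 mean and interannual s.d. of annual mean
  monthly minimum temperature at the record's cell.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .grid import ClimateGrid
from .species import season_window

GROUPINGS = ("species", "species_continent", "global")


def standardize(values, groups) -> np.ndarray:
    """Mean-centre ``values`` within each group.

    Every group must contain at least one non-missing value. Groups are
    centred independently, so the grand mean of the output is generally
    non-zero when group sizes differ.
    """
    s = pd.Series(np.asarray(values, dtype=float))
    g = pd.Series(np.asarray(groups))
    if s.isna().any():
        raise ValueError("cannot standardize missing values")
    if len(s) == 0:
        raise ValueError("cannot standardize an empty sequence")
    counts = s.groupby(g.values).size()
    if (counts < 1).any():
        raise ValueError("every standardization group needs at least one value")
    return (s - s.groupby(g.values).transform("mean")).to_numpy()


def _group_labels(df: pd.DataFrame, grouping: str) -> pd.Series:
    if grouping == "species":
        return df["species"]
    if grouping == "species_continent":
        return df["species"].astype(str) + "|" + df["continent"].astype(str)
    if grouping == "global":
        return pd.Series("all", index=df.index)
    raise ValueError(f"unknown standardization grouping {grouping!r}; use one of {GROUPINGS}")


def extract_site_climate(df: pd.DataFrame, grid: ClimateGrid) -> pd.DataFrame:
    """Raw (uncentred) per-record covariates keyed by record id.

    Adds ``t_seasonal``, ``p_seasonal``, ``mat``, ``ivt`` and the cell
    indices. Raises on records outside the grid or in all-missing cells,
    naming the offending record.
    """
    if "year" not in df.columns or "doy" not in df.columns:
        from .observations import validate_observations

        df = validate_observations(df)
    mat_field = grid.mat_field()
    ivt_field = grid.ivt_field()

    ids = df["id"].to_numpy()
    ilat, ilon = grid.locate_cells(
        df["latitude"].to_numpy(), df["longitude"].to_numpy(), ids=ids
    )
    t_seas = np.empty(len(df))
    p_seas = np.empty(len(df))
    windows = df["species"].map(season_window)
    years = df["year"].to_numpy()
    for (window, year), idx in pd.Series(range(len(df))).groupby(
        [windows.to_numpy(), years], sort=False
    ):
        sel = idx.to_numpy()
        t_field = grid.window_mean_field("tmp", int(year), window)
        p_field = grid.window_mean_field("pre", int(year), window)
        t_seas[sel] = t_field[ilat[sel], ilon[sel]]
        p_seas[sel] = p_field[ilat[sel], ilon[sel]]

    for name, vals in (("temperature", t_seas), ("precipitation", p_seas)):
        if np.isnan(vals).any():
            k = int(np.argmax(np.isnan(vals)))
            raise ValueError(
                f"missing seasonal {name} months for record {ids[k]}"
            )

    out = df.copy()
    out["cell_lat"] = ilat
    out["cell_lon"] = ilon
    out["t_seasonal"] = t_seas
    out["p_seasonal"] = p_seas
    out["mat"] = mat_field[ilat, ilon]
    out["ivt"] = ivt_field[ilat, ilon]
    return out


def attach_covariates(
    df: pd.DataFrame, grid: ClimateGrid, grouping: str = "species"
) -> pd.DataFrame:
    """Full covariate set: raw extraction plus within-group centering."""
    out = extract_site_climate(df, grid)
    labels = _group_labels(out, grouping)
    out["t_std"] = standardize(out["t_seasonal"], labels)
    out["p_std"] = standardize(out["p_seasonal"], labels)
    return out


class ClimateCovariateExtractor(BaseEstimator, TransformerMixin):
    """Transformer attaching climate covariates to an observation table.

    ``fit`` learns the group means used for centering from the fitted table;
    ``transform`` extracts raw covariates for (possibly new) records and
    centres them with the learned means, so train/apply splits share one
    standardization.

    Parameters
    ----------
    grid : ClimateGrid
        Source of monthly climate and long-term normals.
    grouping : str
        Standardization grouping: "species" (default), "species_continent"
        or "global".
    """

    def __init__(self, grid: ClimateGrid | None = None, grouping: str = "species"):
        self.grid = grid
        self.grouping = grouping

    def fit(self, X: pd.DataFrame, y=None):
        if self.grid is None:
            raise ValueError("a ClimateGrid is required")
        raw = extract_site_climate(X, self.grid)
        labels = _group_labels(raw, self.grouping)
        self.t_means_ = raw.groupby(labels.values)["t_seasonal"].mean().to_dict()
        self.p_means_ = raw.groupby(labels.values)["p_seasonal"].mean().to_dict()
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "t_means_"):
            raise ValueError("ClimateCovariateExtractor is not fitted")
        out = extract_site_climate(X, self.grid)
        labels = _group_labels(out, self.grouping)
        unseen = set(labels.unique()) - set(self.t_means_)
        if unseen:
            raise ValueError(f"groups absent from the fitted table: {sorted(unseen)}")
        out["t_std"] = out["t_seasonal"] - labels.map(self.t_means_)
        out["p_std"] = out["p_seasonal"] - labels.map(self.p_means_)
        return out
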