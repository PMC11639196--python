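"""Design matrices for interaction linear models, with analytic structure.

A model is a sum of *terms*, each a product of categorical factors and
numeric covariates; interaction terms expand hierarchically (a product
implies all its marginal sub-products). Factors are treatment-coded against
a reference level, so a term with factors :math:`F_1 \\dots F_k` (with
:math:`L_i` levels) and covariates :math:`c_1 \\dots c_m` contributes
:math:`\\prod_i (L_i - 1)` columns, each the product of level indicator
dummies and covariate values.

Keeping this structure explicit (rather than materializing an opaque
matrix) lets marginal inference evaluate model predictions at arbitrary
variable assignments and differentiate them *exactly* with respect to any
focal covariate: the derivative of a column is the same product with the
focal covariate factor replaced by 1, or zero if the column does not
involve the focal covariate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient; carries the suspect columns."""

    def __init__(self, message: str, columns: list[str]):
        super().__init__(message)
        self.columns = columns


def cross(*variables: str) -> list[tuple[str, ...]]:
    """Hierarchical expansion of a product: all non-empty sub-products."""
    out = []
    for r in range(1, len(variables) + 1):
        out.extend(itertools.combinations(variables, r))
    return out


#: Term structure of the global phenology model: day of year explained by
#: standardized temperature, standardized precipitation and phenophase, each
#: in full interaction with MAT, IVT and species (plus all marginal terms).
GLOBAL_MODEL_PRODUCTS: tuple[tuple[str, ...], ...] = (
    ("t_std", "mat", "ivt", "species"),
    ("p_std", "mat", "ivt", "species"),
    ("phenophase", "mat", "ivt", "species"),
)


@dataclass(frozen=True)
class Term:
    """One model term: a set of factors and a set of covariates."""

    factors: tuple[str, ...]
    covariates: tuple[str, ...]

    @property
    def order(self) -> int:
        return len(self.factors) + len(self.covariates)

    def label(self) -> str:
        return ":".join(self.factors + self.covariates) or "1"


@dataclass(frozen=True)
class Column:
    """One design-matrix column: factor levels crossed with covariates."""

    levels: tuple[tuple[str, str], ...]  # (factor, non-reference level)
    covariates: tuple[str, ...]

    def name(self) -> str:
        parts = [f"{f}[{lv}]" for f, lv in self.levels] + list(self.covariates)
        return ":".join(parts) or "Intercept"

    def evaluate(self, assignment: dict) -> float:
        """Column value at a single variable assignment."""
        v = 1.0
        for f, lv in self.levels:
            if assignment[f] != lv:
                return 0.0
        for c in self.covariates:
            v *= assignment[c]
        return v

    def derivative(self, assignment: dict, focal: tuple[str, ...]) -> float:
        """Partial derivative w.r.t. the (distinct) focal covariates."""
        if len(set(focal)) != len(focal):
            raise ValueError("focal covariates must be distinct")
        if not set(focal) <= set(self.covariates):
            return 0.0
        for f, lv in self.levels:
            if assignment[f] != lv:
                return 0.0
        v = 1.0
        for c in self.covariates:
            if c not in focal:
                v *= assignment[c]
        return v


@dataclass
class ModelSpec:
    """Response, term products and factor coding for a linear model.

    Parameters
    ----------
    response : str
        Name of the response column.
    products : sequence of tuple of str
        Variable products; each expands hierarchically via :func:`cross`.
    factor_levels : dict, optional
        Explicit level order per factor (first level is the reference).
        Factors not listed have levels inferred from data, sorted
        alphabetically, optionally re-rooted by ``reference``.
    reference : dict, optional
        Reference level per factor.
    """

    response: str
    products: tuple[tuple[str, ...], ...]
    factor_levels: dict[str, tuple[str, ...]] = field(default_factory=dict)
    reference: dict[str, str] = field(default_factory=dict)

    def terms(self, factor_names) -> list[Term]:
        seen: dict[frozenset, Term] = {}
        for product in self.products:
            for combo in cross(*product):
                key = frozenset(combo)
                if key in seen:
                    continue
                facs = tuple(v for v in combo if v in factor_names)
                covs = tuple(v for v in combo if v not in factor_names)
                seen[key] = Term(factors=facs, covariates=covs)
        return sorted(seen.values(), key=lambda t: (t.order, t.label()))

    def variables(self) -> list[str]:
        out: list[str] = []
        for product in self.products:
            for v in product:
                if v not in out:
                    out.append(v)
        return out


def aim1_climate_spec(response: str) -> ModelSpec:
    """Additive spatial model for a climate normal: response ~ continent + latitude."""
    return ModelSpec(response=response, products=(("continent",), ("latitude",)))


def aim1_phenology_spec() -> ModelSpec:
    """Spatial phenology model: doy ~ phenophase x (continent + latitude + species)."""
    return ModelSpec(
        response="doy",
        products=(
            ("phenophase", "continent"),
            ("phenophase", "latitude"),
            ("phenophase", "species"),
        ),
    )


def global_model_spec() -> ModelSpec:
    """The global temperature-sensitivity interaction model."""
    return ModelSpec(response="doy", products=GLOBAL_MODEL_PRODUCTS)


class DesignInfo:
    """Resolved design: factor levels, term list and column structure.

    Built once from a data frame; can then evaluate design rows for any
    other assignment of the same variables (used by reference grids).
    """

    def __init__(self, spec: ModelSpec, data: pd.DataFrame):
        self.spec = spec
        names = spec.variables()
        missing = [v for v in names if v not in data.columns]
        if missing:
            raise ValueError(f"data lacks model variables: {missing}")

        self.factor_levels: dict[str, tuple[str, ...]] = {}
        self.covariate_names: list[str] = []
        for v in names:
            col = data[v]
            if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
                levels = spec.factor_levels.get(v)
                if levels is None:
                    levels = tuple(sorted(map(str, pd.unique(col.dropna()))))
                    ref = spec.reference.get(v)
                    if ref is not None:
                        if ref not in levels:
                            raise ValueError(f"reference level {ref!r} not observed in {v!r}")
                        levels = (ref,) + tuple(l for l in levels if l != ref)
                if len(levels) < 2:
                    raise ValueError(
                        f"factor {v!r} has a single observed level {levels}; "
                        "a constant factor cannot be treatment-coded"
                    )
                self.factor_levels[v] = tuple(levels)
            else:
                self.covariate_names.append(v)

        self.terms = spec.terms(set(self.factor_levels))
        self.columns: list[Column] = [Column(levels=(), covariates=())]
        self.term_columns: dict[Term, list[int]] = {Term((), ()): [0]}
        for term in self.terms:
            idx = []
            level_choices = [
                [(f, lv) for lv in self.factor_levels[f][1:]] for f in term.factors
            ]
            for combo in itertools.product(*level_choices):
                self.columns.append(Column(levels=tuple(combo), covariates=term.covariates))
                idx.append(len(self.columns) - 1)
            self.term_columns[term] = idx

        #: Sample means of covariates, used to fix unspecified covariates in
        #: reference grids.
        self.covariate_means = {c: float(data[c].mean()) for c in self.covariate_names}
        self.covariate_ranges = {
            c: (float(data[c].min()), float(data[c].max())) for c in self.covariate_names
        }

    @property
    def column_names(self) -> list[str]:
        return [c.name() for c in self.columns]

    def matrix(self, data: pd.DataFrame) -> np.ndarray:
        """Materialize the design matrix for a data frame."""
        n = len(data)
        X = np.empty((n, len(self.columns)))
        dummies = {
            (f, lv): (data[f].astype(str).to_numpy() == lv).astype(float)
            for f, levels in self.factor_levels.items()
            for lv in levels[1:]
        }
        covs = {c: data[c].to_numpy(dtype=float) for c in self.covariate_names}
        for j, col in enumerate(self.columns):
            v = np.ones(n)
            for f, lv in col.levels:
                v = v * dummies[(f, lv)]
            for c in col.covariates:
                v = v * covs[c]
            X[:, j] = v
        return X

    def row(self, assignment: dict) -> np.ndarray:
        """Design row for a single complete variable assignment."""
        return np.array([c.evaluate(assignment) for c in self.columns])

    def derivative_row(self, assignment: dict, focal: tuple[str, ...]) -> np.ndarray:
        """Row of column derivatives w.r.t. the focal covariates."""
        for f in focal:
            if f not in self.covariate_names:
                raise ValueError(f"focal variable {f!r} is not a covariate of the model")
        return np.array([c.derivative(assignment, focal) for c in self.columns])


def build_design_matrix(
    data: pd.DataFrame, spec: ModelSpec, check_rank: bool = True
) -> tuple[np.ndarray, DesignInfo]:
    """Build the treatment-coded design matrix and its column map.

    Raises :class:`RankDeficiencyError` naming the suspect columns when the
    materialized matrix is rank deficient (silent column dropping would hide
    specification bugs).
    """
    info = DesignInfo(spec, data)
    X = info.matrix(data)
    if check_rank:
        import scipy.linalg

        r = scipy.linalg.qr(X, mode="r", pivoting=True)
        diag = np.abs(np.diag(r[0]))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
        n_ok = int((diag > tol).sum())
        if n_ok < X.shape[1]:
            bad = [info.column_names[j] for j in r[1][n_ok:]]
            raise RankDeficiencyError(
                f"design matrix is rank deficient (rank {n_ok} of {X.shape[1]}); "
                f"suspect columns: {bad}",
                columns=bad,
            )
    return X, info
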