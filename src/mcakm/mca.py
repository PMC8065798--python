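"""Multiple correspondence analysis via SVD of standardized residuals.

Given a patients x variables table of category labels, the analysis
one-hot expands every level of every variable into an indicator matrix
X (each row sums to K, the number of variables), forms the probability
matrix P = X / N with row masses r and column masses c, and takes the
singular value decomposition

    D_r^{-1/2} (P - r c') D_c^{-1/2} = U Delta Q'

Row and column principal coordinates are F = D_r^{-1/2} U Delta and
G = D_c^{-1/2} Q Delta; squared singular values are the eigenvalues
(principal inertias), and their sum is the total inertia, i.e. the
Pearson chi-squared statistic of the table divided by its grand total.
For an indicator matrix the total inertia has the closed form
J/K - 1, with J the total number of category levels.

The same decomposition may be run on the Burt matrix X'X (``basis=
"burt"``), whose eigenvalues are the squares of the indicator-basis
eigenvalues.  Category-level (column) coordinates G are the default
input of the downstream clustering stage, because the method clusters
category levels, not patients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

__all__ = [
    "IndicatorMatrix",
    "CorrespondenceModel",
    "InertiaProfile",
    "encode_indicator",
    "build_burt",
    "fit_ca",
    "fit_mca",
    "inertia_profile",
    "select_dimensions",
    "read_cohort_csv",
    "model_to_json",
    "coordinates_frame",
]

_NULL_TOL = 1e-12


@dataclass
class IndicatorMatrix:
    """0/1 expansion of a categorical table; columns are (variable, level) points."""

    values: np.ndarray
    column_labels: list[tuple[str, str]]
    variable_index: dict[str, slice]
    row_labels: list | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        K = len(self.variable_index)
        if not np.all(self.values.sum(axis=1) == K):
            raise ValueError("each indicator row must activate exactly one level per variable")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    @property
    def n_variables(self) -> int:
        return len(self.variable_index)


def encode_indicator(raw: pd.DataFrame) -> IndicatorMatrix:
    """One-hot expand every observed level of every variable.

    Level order follows the Categorical dtype where present, otherwise
    sorted label order.  A variable with a single observed level has no
    within-variable variation and breaks mass centering, so it is
    rejected with its name.
    """
    if raw.isna().any().any():
        raise ValueError("missing cells are not supported; resolve them upstream")
    blocks = []
    labels: list[tuple[str, str]] = []
    variable_index: dict[str, slice] = {}
    start = 0
    for name in raw.columns:
        col = raw[name]
        if isinstance(col.dtype, pd.CategoricalDtype):
            levels = [lv for lv in col.cat.categories if (col == lv).any()]
        else:
            levels = sorted(col.astype(str).unique())
        if len(levels) < 2:
            raise ValueError(
                f"variable {name!r} has a single observed level; it carries no "
                "information and breaks mass centering"
            )
        block = np.column_stack([(col.astype(str).values == str(lv)) for lv in levels])
        blocks.append(block.astype(float))
        labels.extend((name, str(lv)) for lv in levels)
        variable_index[name] = slice(start, start + len(levels))
        start += len(levels)
    return IndicatorMatrix(
        values=np.hstack(blocks),
        column_labels=labels,
        variable_index=variable_index,
        row_labels=list(raw.index),
    )


def build_burt(X: IndicatorMatrix) -> np.ndarray:
    """Burt matrix X'X: all pairwise two-way contingency tables."""
    return X.values.T @ X.values


@dataclass
class CorrespondenceModel:
    P: np.ndarray
    r: np.ndarray
    c: np.ndarray
    singular_values: np.ndarray
    eigenvalues: np.ndarray
    F: np.ndarray
    G: np.ndarray
    total_inertia: float
    N: float
    basis: str
    column_labels: list[tuple[str, str]]
    row_labels: list | None = None
    n_variables: int | None = None

    @property
    def Dr(self) -> np.ndarray:
        return np.diag(self.r)

    @property
    def Dc(self) -> np.ndarray:
        return np.diag(self.c)

    @property
    def n_dimensions(self) -> int:
        return len(self.singular_values)


def fit_ca(
    table: np.ndarray,
    row_labels=None,
    column_labels=None,
    basis: str = "table",
    n_variables: int | None = None,
) -> CorrespondenceModel:
    """Correspondence analysis of an arbitrary nonnegative two-way table.

    This is the computational core shared by both analysis bases; trivial
    axes (singular value <= 1e-12) are dropped and each retained axis is
    oriented so that its largest-magnitude column loading is positive.
    """
    A = np.asarray(table, dtype=float)
    if A.ndim != 2 or A.shape[0] < 2:
        raise ValueError("need a 2-D table with at least 2 rows")
    if (A < 0).any():
        raise ValueError("table entries must be nonnegative")
    N = A.sum()
    if N <= 0:
        raise ValueError("table has zero grand total")
    P = A / N
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    if (r <= 0).any():
        bad = int(np.flatnonzero(r <= 0)[0])
        name = row_labels[bad] if row_labels is not None else bad
        raise ValueError(f"zero row mass at row {name!r}")
    if (c <= 0).any():
        bad = int(np.flatnonzero(c <= 0)[0])
        name = column_labels[bad] if column_labels is not None else bad
        raise ValueError(f"zero column mass at column {name!r}")

    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = scipy.linalg.svd(S, full_matrices=False)
    keep = sv > _NULL_TOL
    U, sv, V = U[:, keep], sv[keep], Vt[keep].T

    # orient each axis so its largest-|.| column loading is positive
    for s in range(V.shape[1]):
        j = int(np.argmax(np.abs(V[:, s])))
        if V[j, s] < 0:
            V[:, s] = -V[:, s]
            U[:, s] = -U[:, s]

    F = U * sv / np.sqrt(r)[:, None]
    G = V * sv / np.sqrt(c)[:, None]
    return CorrespondenceModel(
        P=P,
        r=r,
        c=c,
        singular_values=sv,
        eigenvalues=sv**2,
        F=F,
        G=G,
        total_inertia=float((S**2).sum()),
        N=float(N),
        basis=basis,
        column_labels=list(column_labels) if column_labels is not None else [],
        row_labels=list(row_labels) if row_labels is not None else None,
        n_variables=n_variables,
    )


def fit_mca(X: IndicatorMatrix, basis: str = "indicator") -> CorrespondenceModel:
    """MCA of an indicator matrix, on the indicator or Burt basis."""
    if basis == "indicator":
        return fit_ca(
            X.values,
            row_labels=X.row_labels,
            column_labels=X.column_labels,
            basis="indicator",
            n_variables=X.n_variables,
        )
    if basis == "burt":
        return fit_ca(
            build_burt(X),
            row_labels=X.column_labels,
            column_labels=X.column_labels,
            basis="burt",
            n_variables=X.n_variables,
        )
    raise ValueError(f"unknown basis {basis!r}; use 'indicator' or 'burt'")


@dataclass
class InertiaProfile:
    eigenvalues: np.ndarray
    proportions: np.ndarray
    cumulative: np.ndarray
    row_point_inertias: np.ndarray
    column_point_inertias: np.ndarray
    n_retained: int


def inertia_profile(model: CorrespondenceModel, subset_dims: int | None = None) -> InertiaProfile:
    """Eigenvalue shares plus per-point inertia contributions.

    Point inertias are mass-weighted squared coordinate norms over the
    retained axes, so the column point inertias sum to the sum of the
    retained eigenvalues (and likewise for rows).
    """
    d = model.n_dimensions if subset_dims is None else int(subset_dims)
    if not 0 <= d <= model.n_dimensions:
        raise ValueError(f"subset_dims {d} outside 0..{model.n_dimensions}")
    eig = model.eigenvalues
    proportions = eig / eig.sum()
    return InertiaProfile(
        eigenvalues=eig,
        proportions=proportions,
        cumulative=np.cumsum(proportions),
        row_point_inertias=model.r * (model.F[:, :d] ** 2).sum(axis=1),
        column_point_inertias=model.c * (model.G[:, :d] ** 2).sum(axis=1),
        n_retained=d,
    )


def select_dimensions(
    profile: InertiaProfile,
    rule: str = "cumulative_threshold",
    threshold: float = 0.8,
) -> int:
    """Number of axes to retain: smallest d reaching the cumulative share."""
    if rule == "all":
        return len(profile.eigenvalues)
    if rule == "cumulative_threshold":
        if not 0 < threshold <= 1:
            raise ValueError("threshold must be in (0, 1]")
        return int(np.searchsorted(profile.cumulative, threshold - 1e-12) + 1)
    raise ValueError(f"unknown rule {rule!r}")


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a categorical cohort CSV (header row, string levels)."""
    df = pd.read_csv(path, dtype=str)
    first = df.columns[0]
    if first.lower() in ("patient_id", "id", "index"):
        df = df.set_index(first)
    return df


def coordinates_frame(model: CorrespondenceModel) -> pd.DataFrame:
    """Column principal coordinates with (variable, level) labels, as a frame."""
    idx = pd.MultiIndex.from_tuples(model.column_labels, names=["variable", "level"])
    cols = [f"dim{i + 1}" for i in range(model.n_dimensions)]
    return pd.DataFrame(model.G, index=idx, columns=cols)


def model_to_json(model: CorrespondenceModel, path=None) -> str:
    payload = {
        "basis": model.basis,
        "N": model.N,
        "n_variables": model.n_variables,
        "column_labels": [list(t) for t in model.column_labels],
        "row_mass": model.r.tolist(),
        "column_mass": model.c.tolist(),
        "singular_values": model.singular_values.tolist(),
        "eigenvalues": model.eigenvalues.tolist(),
        "total_inertia": model.total_inertia,
        "column_coordinates": model.G.tolist(),
    }
    text = json.dumps(payload, indent=1)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
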