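"""Additive main effects and multiplicative interaction (AMMI) analysis.

The two-way table of cell means is modelled as

    Y_ij = mu + alpha_i + beta_j + sum_k lambda_k * xi_ik * eta_kj + eps_ij

where rows are rhizobium strains (playing the classical "genotype" role)
and columns are bean genotypes (playing "environments").  The additive
main effects are removed by double centering and the residual interaction
matrix Z is decomposed by SVD.  Axis k carries

    SS_k = r * lambda_k**2        (r = replicates behind each cell mean)
    df_k = n_rows + n_cols - 1 - 2k   (Gollob's rule)

so that the axis sums of squares add up exactly to the plot-level
interaction SS of the factorial ANOVA.  Axis F tests divide MS_k by the
ANOVA residual mean square; Gollob's test is known to be liberal, which is
fine for the descriptive use made of it here.

Sign convention: the largest-magnitude element of each left singular
vector is made positive, so scores are reproducible across SVD backends.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "AmmiResult",
    "BiplotCoords",
    "AmmiModel",
    "double_center",
    "gollob_df",
    "ammi_decompose",
    "ammi_f_tests",
    "biplot_coords",
]

_CENTER_TOL = 1e-8


def gollob_df(n_rows: int, n_cols: int, axis: int) -> int:
    """Degrees of freedom of interaction axis ``axis`` (1-based): g + e - 1 - 2k.

    For the 8-strain x 10-genotype jar table the seven axes carry
    15, 13, 11, 9, 7, 5, 3 df; for the 6 x 5 subset tables, 8, 6, 4, 2.
    """
    k_max = min(n_rows - 1, n_cols - 1)
    if not 1 <= axis <= k_max:
        raise ValueError(f"axis must lie in [1, {k_max}], got {axis}")
    return n_rows + n_cols - 1 - 2 * axis


def double_center(cell_means) -> tuple[np.ndarray, float, np.ndarray, np.ndarray]:
    """Remove row, column and grand means from a two-way table.

    Returns ``(Z, mu, alpha, beta)`` with ``Z[i,j] = Y[i,j] - rowmean_i -
    colmean_j + mu``; ``alpha`` (row effects) and ``beta`` (column effects)
    each sum to zero, and every row and column of Z sums to zero.
    """
    Y = np.asarray(cell_means, dtype=float)
    if Y.ndim != 2 or Y.shape[0] < 2 or Y.shape[1] < 2:
        raise ValueError("cell-mean table must be 2-D with >= 2 rows and >= 2 columns")
    if np.isnan(Y).any():
        raise ValueError("cell-mean table contains missing values")
    mu = float(Y.mean())
    alpha = Y.mean(axis=1) - mu
    beta = Y.mean(axis=0) - mu
    Z = Y - mu - alpha[:, None] - beta[None, :]
    return Z, mu, alpha, beta


@dataclass
class AmmiResult:
    """Full AMMI decomposition of one strain x genotype response table."""

    grand_mean: float
    row_effects: pd.Series
    col_effects: pd.Series
    interaction: pd.DataFrame
    singular_values: np.ndarray
    row_scores: pd.DataFrame  # strains x axes, orthonormal columns
    col_scores: pd.DataFrame  # axes x genotypes, orthonormal rows
    n_axes: int
    replicates: int
    axis_table: Optional[pd.DataFrame] = None

    @property
    def n_max_axes(self) -> int:
        return len(self.singular_values)

    @property
    def axis_df(self) -> np.ndarray:
        g, e = self.interaction.shape
        return np.array([gollob_df(g, e, k) for k in range(1, self.n_max_axes + 1)])

    @property
    def axis_ss(self) -> np.ndarray:
        """Per-axis SS on the plot level: replicates * lambda_k**2."""
        return self.replicates * self.singular_values**2

    def reconstruct(self, n_axes: Optional[int] = None) -> np.ndarray:
        """Rank-``n_axes`` approximation of the interaction matrix."""
        t = self.n_max_axes if n_axes is None else n_axes
        U = self.row_scores.values[:, :t]
        V = self.col_scores.values[:t, :]
        return (U * self.singular_values[:t]) @ V


@dataclass(frozen=True)
class BiplotCoords:
    """Symmetric-scaling biplot coordinates on the first two axes.

    The inner product of a strain point and a genotype point over the two
    axes approximates that cell's interaction effect.  ``degenerate`` marks
    a second axis with zero singular value (all second coordinates 0).
    """

    frame: pd.DataFrame  # columns: label, kind (strain|genotype), dim1, dim2
    scaling: str = "symmetric"
    degenerate: bool = False

    @property
    def points(self) -> dict[str, tuple[float, float]]:
        return {
            row.label: (row.dim1, row.dim2) for row in self.frame.itertuples(index=False)
        }


def _svd_fixed_sign(Z: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    U, svals, Vt = np.linalg.svd(Z, full_matrices=False)
    k_max = min(Z.shape[0] - 1, Z.shape[1] - 1)
    U, svals, Vt = U[:, :k_max], svals[:k_max], Vt[:k_max]
    for k in range(k_max):
        j = int(np.argmax(np.abs(U[:, k])))
        if U[j, k] < 0:
            U[:, k] = -U[:, k]
            Vt[k] = -Vt[k]
    return U, svals, Vt


class AmmiModel(BaseEstimator):
    """AMMI decomposition of a strain x genotype cell-mean table.

    Parameters
    ----------
    n_axes : int
        Number of multiplicative axes retained for reporting (biplots use
        2); all ``min(g-1, e-1)`` axes remain available on the result.
    replicates : int
        Plots behind each cell mean; scales axis SS to the plot level so
        they sum to the factorial-ANOVA interaction SS.  Use 1 when only
        means exist.

    Attributes
    ----------
    grand_mean_, row_effects_, col_effects_ : additive components.
    interaction_ : pandas.DataFrame
        Double-centered interaction matrix Z.
    singular_values_ : ndarray, descending.
    row_scores_, col_scores_ : orthonormal axis scores.
    result_ : AmmiResult

    Examples
    --------
    >>> m = AmmiModel(n_axes=2, replicates=5).fit(cell_means)   # doctest: +SKIP
    >>> m.f_tests(residual_ms, residual_df)                     # doctest: +SKIP
    """

    def __init__(self, n_axes: int = 2, replicates: int = 1):
        self.n_axes = n_axes
        self.replicates = replicates

    def fit(self, X, y=None) -> "AmmiModel":
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if isinstance(X, pd.DataFrame):
            rows = list(X.index)
            cols = list(X.columns)
        else:
            X = np.asarray(X, dtype=float)
            rows = [f"row{i}" for i in range(X.shape[0])] if X.ndim == 2 else []
            cols = [f"col{j}" for j in range(X.shape[1])] if X.ndim == 2 else []
        Z, mu, alpha, beta = double_center(X)
        U, svals, Vt = _svd_fixed_sign(Z)
        k_max = len(svals)
        if not 0 <= self.n_axes:
            raise ValueError("n_axes must be >= 0")
        axes = [f"axis{k}" for k in range(1, k_max + 1)]
        self.grand_mean_ = mu
        self.row_effects_ = pd.Series(alpha, index=rows, name="row_effect")
        self.col_effects_ = pd.Series(beta, index=cols, name="col_effect")
        self.interaction_ = pd.DataFrame(Z, index=rows, columns=cols)
        self.singular_values_ = svals
        self.row_scores_ = pd.DataFrame(U, index=rows, columns=axes)
        self.col_scores_ = pd.DataFrame(Vt, index=axes, columns=cols)
        self.n_axes_ = min(self.n_axes, k_max)
        self.result_ = AmmiResult(
            grand_mean=mu,
            row_effects=self.row_effects_,
            col_effects=self.col_effects_,
            interaction=self.interaction_,
            singular_values=svals,
            row_scores=self.row_scores_,
            col_scores=self.col_scores_,
            n_axes=self.n_axes_,
            replicates=self.replicates,
        )
        return self

    def f_tests(self, residual_ms: float, residual_df: int) -> pd.DataFrame:
        """Gollob axis F tests against the factorial-ANOVA residual."""
        table = ammi_f_tests(self.result_, residual_ms, residual_df)
        self.result_.axis_table = table
        return table

    def biplot_coords(self) -> BiplotCoords:
        return biplot_coords(self.result_)

    def reconstruct(self, n_axes: Optional[int] = None) -> np.ndarray:
        return self.result_.reconstruct(n_axes)


def ammi_decompose(Z, replicates: int = 1, n_axes: int = 2) -> AmmiResult:
    """Decompose an already double-centered interaction matrix.

    Row and column sums of ``Z`` must vanish (tolerance scaled to the
    matrix magnitude); pass cell means through :func:`double_center` or use
    :class:`AmmiModel` directly for uncentered tables.
    """
    values = Z.values if isinstance(Z, pd.DataFrame) else np.asarray(Z, dtype=float)
    scale = max(1.0, float(np.abs(values).max()) if values.size else 1.0)
    if (
        np.abs(values.sum(axis=0)).max() > _CENTER_TOL * scale * values.shape[0]
        or np.abs(values.sum(axis=1)).max() > _CENTER_TOL * scale * values.shape[1]
    ):
        raise ValueError("matrix is not double-centered; row/column sums exceed tolerance")
    model = AmmiModel(n_axes=n_axes, replicates=replicates).fit(Z)
    return model.result_


def ammi_f_tests(
    result: AmmiResult, residual_ms: float, residual_df: int
) -> pd.DataFrame:
    """Per-axis df, SS, MS, F and p for an AMMI decomposition.

    MS_k = SS_k / df_k with SS_k = r * lambda_k**2; F_k = MS_k / residual
    MS of the matching factorial ANOVA; p from F(df_k, residual_df).  With
    residual_df <= 0 the p column is None.
    """
    dfs = result.axis_df
    ss = result.axis_ss
    ms = ss / dfs
    rows = []
    for k in range(result.n_max_axes):
        f = p = None
        if residual_ms is not None and residual_ms > 0:
            f = float(ms[k] / residual_ms)
            if residual_df > 0:
                p = float(stats.f.sf(f, dfs[k], residual_df))
        rows.append(
            {
                "axis": k + 1,
                "df": int(dfs[k]),
                "ss": float(ss[k]),
                "ms": float(ms[k]),
                "f": f,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def biplot_coords(result: AmmiResult) -> BiplotCoords:
    """Symmetric-scaling coordinates on the first two axes.

    Strain k-coordinate ``xi_ik * sqrt(lambda_k)``; genotype k-coordinate
    ``eta_kj * sqrt(lambda_k)`` — the product over retained axes then
    reconstructs the interaction effect.
    """
    if result.n_max_axes < 2:
        raise ValueError("need at least 2 interaction axes for a biplot")
    lam = result.singular_values[:2].copy()
    degenerate = bool(lam[1] <= 1e-10 * max(lam[0], 1.0))
    if degenerate:
        lam[1] = 0.0
    sq = np.sqrt(lam)
    rows = []
    for i, label in enumerate(result.row_scores.index):
        rows.append(
            {
                "label": label,
                "kind": "strain",
                "dim1": result.row_scores.iloc[i, 0] * sq[0],
                "dim2": result.row_scores.iloc[i, 1] * sq[1],
            }
        )
    for j, label in enumerate(result.col_scores.columns):
        rows.append(
            {
                "label": label,
                "kind": "genotype",
                "dim1": result.col_scores.iloc[0, j] * sq[0],
                "dim2": result.col_scores.iloc[1, j] * sq[1],
            }
        )
    return BiplotCoords(frame=pd.DataFrame(rows), degenerate=degenerate)
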