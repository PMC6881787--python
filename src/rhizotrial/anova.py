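"""Factorial RCBD ANOVA for genotype x strain trials.

Balanced two-factor trials with replicate as a blocking factor are
decomposed by the classical closed-form sums of squares::

    y_ijk = mu + rep_k + genotype_j + strain_i + (genotype x strain)_ij + e_ijk

The sequential (type I) decomposition is computed exactly from marginal
totals; on a balanced layout the factor terms are mutually orthogonal, so
the order among Genotype and Strain is immaterial.  F tests for the fixed
terms use the residual mean square, which for a balanced RCBD coincides
with the replicate-as-random mixed-model tests.

A second model contrasts *groups* of genotypes (genepool, growth habit,
origin): genotypes nest in groups, and the group terms are tested against
the corresponding within-group genotype terms (expected-mean-squares
tests), not against the plot residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .io import inoculated_only

__all__ = [
    "AnovaRow",
    "AnovaTable",
    "BalanceError",
    "MissingCellError",
    "GroupModelSpec",
    "FactorialAnova",
    "GroupAnova",
    "fit_factorial_rcbd",
    "fit_group_model",
    "cell_means",
    "p_stars",
]


class BalanceError(ValueError):
    """The layout is not a complete balanced factorial RCBD."""


class MissingCellError(ValueError):
    """A genotype x strain cell has no observations."""


def p_stars(p: Optional[float]) -> str:
    """Significance stars: *** <0.001, ** <0.01, * <0.05, . <0.1."""
    if p is None or np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "."
    return ""


@dataclass(frozen=True)
class AnovaRow:
    source: str
    df: int
    ss: float
    ms: Optional[float]
    f: Optional[float]
    p: Optional[float]


@dataclass
class AnovaTable:
    """Ordered ANOVA rows for one response, with the error-term mapping used."""

    rows: list[AnovaRow]
    response: str
    error_term_map: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, source: str) -> AnovaRow:
        for row in self.rows:
            if row.source == source:
                return row
        raise KeyError(source)

    @property
    def sources(self) -> list[str]:
        return [r.source for r in self.rows]

    @property
    def total_ss(self) -> float:
        return float(sum(r.ss for r in self.rows))

    @property
    def total_df(self) -> int:
        return int(sum(r.df for r in self.rows))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": [r.source for r in self.rows],
                "df": [r.df for r in self.rows],
                "ss": [r.ss for r in self.rows],
                "ms": [r.ms for r in self.rows],
                "f": [r.f for r in self.rows],
                "p": [r.p for r in self.rows],
                "stars": [p_stars(r.p) for r in self.rows],
            }
        )

    def to_text(self) -> str:
        """Aligned plain-text rendering (source, df, MS, F, p, stars)."""
        lines = [f"Response: {self.response}"]
        header = f"{'Source':<28}{'DF':>5}{'MS':>12}{'F':>10}{'p':>10}  "
        lines.append(header)
        for r in self.rows:
            ms = f"{r.ms:.4g}" if r.ms is not None else "-"
            fv = f"{r.f:.3f}" if r.f is not None else "-"
            pv = f"{r.p:.4g}" if r.p is not None else "-"
            lines.append(
                f"{r.source:<28}{r.df:>5}{ms:>12}{fv:>10}{pv:>10}  {p_stars(r.p)}"
            )
        return "\n".join(lines)


@dataclass(frozen=True)
class GroupModelSpec:
    """Grouping of genotypes (e.g. genepool) for the group-contrast model."""

    grouping: str
    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(set(self.mapping.values())) < 2:
            raise ValueError("grouping needs at least 2 groups")


def _prepare(records: pd.DataFrame, response: str) -> pd.DataFrame:
    df = inoculated_only(records)
    for col in ("genotype", "treatment", "replicate", response):
        if col not in df.columns:
            raise KeyError(f"records lack required column {col!r}")
    if df[response].isna().any():
        raise ValueError(f"response {response!r} contains missing values")
    return df


def _check_balance(df: pd.DataFrame, unbalanced: str, response: str) -> tuple[pd.DataFrame, int]:
    """Return a complete balanced frame and the number of imputed plots."""
    genotypes = pd.unique(df["genotype"])
    strains = pd.unique(df["treatment"])
    reps = np.sort(pd.unique(df["replicate"]))
    full = pd.MultiIndex.from_product(
        [strains, genotypes, reps], names=["treatment", "genotype", "replicate"]
    )
    counts = df.groupby(["treatment", "genotype", "replicate"]).size()
    if (counts > 1).any():
        raise BalanceError("multiple observations for one (strain, genotype, replicate) unit")
    observed = counts.reindex(full, fill_value=0)
    n_missing = int((observed == 0).sum())
    if n_missing == 0:
        return df, 0
    if unbalanced != "impute":
        raise BalanceError(
            f"{n_missing} missing plot(s); layout is not a complete balanced RCBD"
        )
    cell_mean = df.groupby(["treatment", "genotype"])[response].mean()
    fills = []
    for strain, genotype, rep in full[observed.values == 0]:
        if (strain, genotype) not in cell_mean.index:
            raise MissingCellError(f"cell (strain={strain!r}, genotype={genotype!r}) is empty")
        fills.append(
            {
                "treatment": strain,
                "genotype": genotype,
                "replicate": rep,
                response: cell_mean.loc[(strain, genotype)],
            }
        )
    df = pd.concat([df, pd.DataFrame(fills)], ignore_index=True)
    return df, n_missing


def _marginal_ss(df: pd.DataFrame, response: str, by: Sequence[str], per: int, C: float) -> float:
    totals = df.groupby(list(by), sort=False)[response].sum()
    return float((totals**2).sum() / per - C)


class FactorialAnova(BaseEstimator):
    """Sequential (type I) factorial RCBD ANOVA for one response.

    Parameters
    ----------
    response : str
        Response column; one of the raw or derived phenotypes
        (``rsdw``, ``nodule_number``, ``nodule_dw``, ``ndfa``, ``rndfa``,
        ``sdw``, ...).
    unbalanced : {"error", "impute"}
        Policy for incomplete layouts.  ``impute`` replaces missing plots
        by their cell mean and subtracts the number imputed from the
        residual df; wholly empty cells always raise.

    Attributes
    ----------
    table_ : AnovaTable
        Rows Rep, Genotype, Strain, Genotype x Strain, Residual.
    cell_means_ : pandas.DataFrame
        Strain x genotype matrix of cell means.
    residual_ms_, residual_df_ : float, int
        Error line, as consumed by the AMMI axis F tests.
    """

    SOURCES = ("Rep", "Genotype", "Strain", "Genotype x Strain", "Residual")

    def __init__(self, response: str = "rsdw", unbalanced: str = "error"):
        self.response = response
        self.unbalanced = unbalanced

    def fit(self, X: pd.DataFrame, y=None) -> "FactorialAnova":
        if self.unbalanced not in ("error", "impute"):
            raise ValueError("unbalanced must be 'error' or 'impute'")
        df = _prepare(X, self.response)
        df, n_imputed = _check_balance(df, self.unbalanced, self.response)
        resp = self.response

        genotypes = pd.unique(df["genotype"])
        strains = pd.unique(df["treatment"])
        g, s = len(genotypes), len(strains)
        r = df["replicate"].nunique()
        if g < 2 or s < 2:
            raise ValueError("need at least 2 genotypes and 2 strains")
        N = g * s * r
        y_all = df[resp].to_numpy(dtype=float)
        C = y_all.sum() ** 2 / N
        ss_total = float((y_all**2).sum() - C)

        ss_rep = _marginal_ss(df, resp, ["replicate"], g * s, C)
        ss_g = _marginal_ss(df, resp, ["genotype"], s * r, C)
        ss_s = _marginal_ss(df, resp, ["treatment"], g * r, C)
        ss_cells = _marginal_ss(df, resp, ["treatment", "genotype"], r, C)
        ss_gs = ss_cells - ss_g - ss_s
        ss_res = ss_total - ss_rep - ss_g - ss_s - ss_gs

        df_rep, df_g, df_s = r - 1, g - 1, s - 1
        df_gs = (g - 1) * (s - 1)
        df_res = (g * s - 1) * (r - 1) - n_imputed
        if df_res < 0:
            raise BalanceError("imputation exhausted the residual degrees of freedom")

        ms_res = ss_res / df_res if df_res > 0 else None

        def row(source: str, dfree: int, ss: float, tested: bool) -> AnovaRow:
            ms = ss / dfree if dfree > 0 else None
            f = p = None
            if tested and ms is not None and ms_res is not None and ms_res > 0:
                f = ms / ms_res
                p = float(stats.f.sf(f, dfree, df_res))
            return AnovaRow(source, dfree, max(ss, 0.0) if ss > -1e-12 else ss, ms, f, p)

        rows = [
            row("Rep", df_rep, ss_rep, False),
            row("Genotype", df_g, ss_g, True),
            row("Strain", df_s, ss_s, True),
            row("Genotype x Strain", df_gs, ss_gs, True),
            AnovaRow("Residual", df_res, ss_res, ms_res, None, None),
        ]
        self.table_ = AnovaTable(
            rows=rows,
            response=resp,
            error_term_map={
                "Genotype": "Residual",
                "Strain": "Residual",
                "Genotype x Strain": "Residual",
            },
        )
        self.genotypes_ = list(genotypes)
        self.strains_ = list(strains)
        self.n_replicates_ = int(r)
        self.n_imputed_ = n_imputed
        self.cell_means_ = (
            df.pivot_table(index="treatment", columns="genotype", values=resp, aggfunc="mean")
            .reindex(index=strains, columns=genotypes)
        )
        self.interaction_ss_ = ss_gs
        self.residual_ms_ = ms_res
        self.residual_df_ = df_res
        return self


class GroupAnova(BaseEstimator):
    """Group-contrast RCBD ANOVA with genotypes nested in groups.

    Sources: Rep, Group, Genotype(Group), Strain, Group x Strain,
    Genotype x Strain(Group), Residual.  Expected-mean-squares tests:
    Group against Genotype(Group); Strain and Group x Strain against
    Genotype x Strain(Group) — the genotype terms act as random error
    strata for the group-level contrasts.  A contrast whose error stratum
    has 0 df is reported untestable (F and p are None), never dropped.
    """

    def __init__(
        self,
        mapping: Optional[Mapping[str, str]] = None,
        response: str = "rsdw",
        grouping: str = "group",
    ):
        self.mapping = mapping
        self.response = response
        self.grouping = grouping

    def fit(self, X: pd.DataFrame, y=None) -> "GroupAnova":
        if not self.mapping:
            raise ValueError("a genotype -> group mapping is required")
        df = _prepare(X, self.response)
        df, n_imputed = _check_balance(df, "error", self.response)
        resp = self.response

        genotypes = pd.unique(df["genotype"])
        unmapped = [gt for gt in genotypes if gt not in self.mapping]
        if unmapped:
            raise KeyError(f"genotype(s) not mapped to a group: {unmapped}")
        df = df.assign(group=df["genotype"].map(dict(self.mapping)))
        groups = pd.unique(df["group"])
        if len(groups) < 2:
            raise ValueError("grouping needs at least 2 groups present in the data")

        strains = pd.unique(df["treatment"])
        g, s, k = len(genotypes), len(strains), len(groups)
        r = df["replicate"].nunique()
        N = g * s * r
        y_all = df[resp].to_numpy(dtype=float)
        C = y_all.sum() ** 2 / N
        ss_total = float((y_all**2).sum() - C)

        # group sizes enter through per-group totals: groups may hold
        # unequal numbers of genotypes while the g x s x r grid stays balanced
        n_per_group = df.groupby("group", sort=False)["genotype"].nunique()

        def weighted_ss(by: Sequence[str], weights: pd.Series) -> float:
            totals = df.groupby(list(by), sort=False)[resp].sum()
            w = weights.reindex(totals.index.get_level_values("group"))
            return float((totals**2 / w.to_numpy()).sum() - C)

        ss_rep = _marginal_ss(df, resp, ["replicate"], g * s, C)
        ss_group = weighted_ss(["group"], n_per_group * s * r)
        ss_geno = _marginal_ss(df, resp, ["genotype"], s * r, C)
        ss_geno_within = ss_geno - ss_group
        ss_strain = _marginal_ss(df, resp, ["treatment"], g * r, C)
        ss_group_strain = (
            weighted_ss(["group", "treatment"], n_per_group * r)
            - ss_group
            - ss_strain
        )
        ss_cells = _marginal_ss(df, resp, ["treatment", "genotype"], r, C)
        ss_gs_total = ss_cells - ss_geno - ss_strain
        ss_gs_within = ss_gs_total - ss_group_strain
        ss_res = ss_total - ss_rep - ss_geno - ss_strain - ss_gs_total

        df_rep = r - 1
        df_group = k - 1
        df_geno_within = g - k
        df_strain = s - 1
        df_group_strain = (k - 1) * (s - 1)
        df_gs_within = (g - k) * (s - 1)
        df_res = (g * s - 1) * (r - 1)

        def ms(ss: float, dfree: int) -> Optional[float]:
            return ss / dfree if dfree > 0 else None

        ms_geno_within = ms(ss_geno_within, df_geno_within)
        ms_gs_within = ms(ss_gs_within, df_gs_within)

        def tested(source: str, dfree: int, ss: float, err_ms, err_df) -> AnovaRow:
            m = ms(ss, dfree)
            f = p = None
            if m is not None and err_ms is not None and err_df > 0 and err_ms > 0:
                f = m / err_ms
                p = float(stats.f.sf(f, dfree, err_df))
            return AnovaRow(source, dfree, ss, m, f, p)

        geno_lbl = "Genotype(Group)"
        gsw_lbl = "Genotype x Strain(Group)"
        rows = [
            AnovaRow("Rep", df_rep, ss_rep, ms(ss_rep, df_rep), None, None),
            tested("Group", df_group, ss_group, ms_geno_within, df_geno_within),
            AnovaRow(geno_lbl, df_geno_within, ss_geno_within, ms_geno_within, None, None),
            tested("Strain", df_strain, ss_strain, ms_gs_within, df_gs_within),
            tested("Group x Strain", df_group_strain, ss_group_strain, ms_gs_within, df_gs_within),
            AnovaRow(gsw_lbl, df_gs_within, ss_gs_within, ms_gs_within, None, None),
            AnovaRow("Residual", df_res, ss_res, ms(ss_res, df_res), None, None),
        ]
        self.table_ = AnovaTable(
            rows=rows,
            response=resp,
            error_term_map={
                "Group": geno_lbl,
                "Strain": gsw_lbl,
                "Group x Strain": gsw_lbl,
            },
        )
        self.groups_ = list(groups)
        self.genotypes_ = list(genotypes)
        self.strains_ = list(strains)
        self.n_replicates_ = int(r)
        return self


def fit_factorial_rcbd(
    records: pd.DataFrame, response: str = "rsdw", unbalanced: str = "error"
) -> AnovaTable:
    """Fit the factorial RCBD model and return its ANOVA table."""
    return FactorialAnova(response=response, unbalanced=unbalanced).fit(records).table_


def fit_group_model(
    records: pd.DataFrame, spec: GroupModelSpec, response: str = "rsdw"
) -> AnovaTable:
    """Fit the group-contrast model for a genotype grouping."""
    return (
        GroupAnova(mapping=dict(spec.mapping), response=response, grouping=spec.grouping)
        .fit(records)
        .table_
    )


def cell_means(records: pd.DataFrame, response: str = "rsdw") -> pd.DataFrame:
    """Strain x genotype matrix of per-cell arithmetic means.

    Every cell must be non-empty; an empty cell raises ``MissingCellError``
    naming it.
    """
    df = inoculated_only(records)
    if response not in df.columns:
        raise KeyError(f"records lack response column {response!r}")
    strains = pd.unique(df["treatment"])
    genotypes = pd.unique(df["genotype"])
    mat = (
        df.pivot_table(index="treatment", columns="genotype", values=response, aggfunc="mean")
        .reindex(index=strains, columns=genotypes)
    )
    if mat.isna().any().any():
        i, j = np.argwhere(mat.isna().values)[0]
        raise MissingCellError(
            f"cell (strain={mat.index[i]!r}, genotype={mat.columns[j]!r}) is empty"
        )
    mat.index.name = "strain"
    mat.columns.name = "genotype"
    return mat
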