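"""Derived symbiotic quantities: RSE/RSDW, total shoot N, Ndfa, RNdfa.

All metrics are genotype-relative: bean genotypes differ strongly in seed
size and inherent vigour, so raw shoot biomass is normalised against that
genotype's own uninoculated controls.

* total shoot N:  TSN = SDW * %N / 100  (grams)
* Ndfa (N-difference method): TSN of an inoculated plant minus the mean TSN
  of the genotype's negative (unfertilised, uninoculated) controls.
* RNdfa: Ndfa divided by mean TSN of the N-fertilised positive controls.
* RSE (relative symbiotic efficiency, a.k.a. relative shoot dry weight,
  RSDW): (SDW_inoculated - mean SDW of negative controls) / mean SDW of
  positive controls.  The positive-control denominator (rather than the
  classical positive-minus-negative difference) keeps the ratio stable when
  controls perform similarly.

Negative Ndfa or RSE values are reported as-is, never clipped, so that the
downstream ANOVA noise stays symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .design import NEGATIVE_CONTROL, POSITIVE_CONTROL
from .io import inoculated_only

__all__ = [
    "GenotypeBaselines",
    "DegenerateBaselineError",
    "BaselineLookupError",
    "compute_baselines",
    "total_shoot_n",
    "ndfa",
    "rndfa",
    "rse",
    "add_derived_responses",
    "ScoreMatrix",
    "phenotype_score_matrix",
]


class DegenerateBaselineError(ValueError):
    """A control mean required as a denominator is zero or negative."""


class BaselineLookupError(KeyError):
    """No control baseline is available for the requested genotype."""


@dataclass(frozen=True)
class GenotypeBaselines:
    """Per-genotype control means used to normalise symbiotic performance."""

    genotype: str
    sdw_neg_mean: float
    sdw_pos_mean: float
    tsn_neg_mean: Optional[float] = None
    tsn_pos_mean: Optional[float] = None


def total_shoot_n(sdw, n_percent):
    """Total shoot nitrogen in grams: ``sdw * n_percent / 100``.

    Accepts scalars or arrays; ``n_percent`` outside [0, 100] is rejected.
    """
    sdw = np.asarray(sdw, dtype=float)
    n_percent = np.asarray(n_percent, dtype=float)
    valid = np.isnan(n_percent) | ((n_percent >= 0) & (n_percent <= 100))
    if not np.all(valid):
        raise ValueError("n_percent must lie in [0, 100]")
    out = sdw * n_percent / 100.0
    return float(out) if out.ndim == 0 else out


def ndfa(tsn_in: float, baseline: GenotypeBaselines) -> float:
    """N derived from the atmosphere by the N-difference method (grams).

    ``tsn_in - tsn_neg_mean`` for the same genotype; may be negative.
    """
    if baseline.tsn_neg_mean is None or np.isnan(baseline.tsn_neg_mean):
        raise BaselineLookupError(
            f"genotype {baseline.genotype!r} has no negative-control TSN baseline"
        )
    return tsn_in - baseline.tsn_neg_mean


def rndfa(ndfa_g: float, baseline: GenotypeBaselines) -> float:
    """Relative fixed N: Ndfa over mean TSN of the N-fed positive controls."""
    if baseline.tsn_pos_mean is None or np.isnan(baseline.tsn_pos_mean):
        raise BaselineLookupError(
            f"genotype {baseline.genotype!r} has no positive-control TSN baseline"
        )
    if baseline.tsn_pos_mean <= 0:
        raise DegenerateBaselineError(
            f"positive-control TSN for {baseline.genotype!r} must be > 0"
        )
    return ndfa_g / baseline.tsn_pos_mean


def rse(sdw_inoculated: float, baseline: GenotypeBaselines) -> float:
    """Relative symbiotic efficiency (= relative shoot dry weight, RSDW).

    ``(sdw_inoculated - sdw_neg_mean) / sdw_pos_mean``; the positive-control
    denominator never approaches zero the way a positive-minus-negative
    difference can, so the ratio stays well behaved under replicate noise.
    """
    if np.isnan(baseline.sdw_pos_mean) or baseline.sdw_pos_mean <= 0:
        raise DegenerateBaselineError(
            f"positive-control SDW for {baseline.genotype!r} must be > 0"
        )
    return (sdw_inoculated - baseline.sdw_neg_mean) / baseline.sdw_pos_mean


def compute_baselines(
    records: pd.DataFrame, replicate_matched: bool = False
) -> dict[str, GenotypeBaselines]:
    """Control means per genotype from a single-experiment trial table.

    Means are taken across all replicates of each control treatment (the
    genotype-level reading; set ``replicate_matched=True`` only when pairing
    by replicate is explicitly wanted — then per-replicate baselines are
    averaged, which coincides with the default for balanced controls).
    TSN baselines are filled only where ``n_percent`` is measured on the
    controls.
    """
    if records["experiment"].nunique() > 1:
        raise ValueError("baselines must be computed within one experiment")
    out: dict[str, GenotypeBaselines] = {}
    controls = records[records["treatment"].isin((POSITIVE_CONTROL, NEGATIVE_CONTROL))]
    tsn = total_shoot_n(controls["sdw"], controls["n_percent"])
    controls = controls.assign(_tsn=tsn)
    for genotype, sub in controls.groupby("genotype", sort=False):
        neg = sub[sub["treatment"] == NEGATIVE_CONTROL]
        pos = sub[sub["treatment"] == POSITIVE_CONTROL]
        if neg.empty or pos.empty:
            raise BaselineLookupError(
                f"genotype {genotype!r} lacks positive or negative controls"
            )
        if replicate_matched:
            sdw_neg = float(neg.groupby("replicate")["sdw"].mean().mean())
            sdw_pos = float(pos.groupby("replicate")["sdw"].mean().mean())
        else:
            sdw_neg = float(neg["sdw"].mean())
            sdw_pos = float(pos["sdw"].mean())
        out[str(genotype)] = GenotypeBaselines(
            genotype=str(genotype),
            sdw_neg_mean=sdw_neg,
            sdw_pos_mean=sdw_pos,
            tsn_neg_mean=float(neg["_tsn"].mean()) if neg["_tsn"].notna().all() else None,
            tsn_pos_mean=float(pos["_tsn"].mean()) if pos["_tsn"].notna().all() else None,
        )
    return out


def add_derived_responses(
    records: pd.DataFrame,
    baselines: Optional[Mapping[str, GenotypeBaselines]] = None,
) -> pd.DataFrame:
    """Attach rsdw (and tsn/ndfa/rndfa where %N is measured) to a trial table.

    Derived columns are computed for every row, controls included; rows of a
    genotype with no baseline raise.  N-based columns are added only when
    every inoculated row carries ``n_percent``.
    """
    if baselines is None:
        baselines = compute_baselines(records)
    df = records.copy()
    missing = set(df["genotype"]) - set(baselines)
    if missing:
        raise BaselineLookupError(f"no baselines for genotype(s) {sorted(missing)}")
    neg_sdw = df["genotype"].map({g: b.sdw_neg_mean for g, b in baselines.items()})
    pos_sdw = df["genotype"].map({g: b.sdw_pos_mean for g, b in baselines.items()})
    if (pos_sdw <= 0).any():
        bad = df.loc[pos_sdw <= 0, "genotype"].iloc[0]
        raise DegenerateBaselineError(f"positive-control SDW for {bad!r} must be > 0")
    df["rsdw"] = (df["sdw"] - neg_sdw) / pos_sdw

    has_n = inoculated_only(df)["n_percent"].notna().all() and len(inoculated_only(df)) > 0
    tsn_neg = {g: b.tsn_neg_mean for g, b in baselines.items()}
    tsn_pos = {g: b.tsn_pos_mean for g, b in baselines.items()}
    if has_n and all(v is not None for v in tsn_neg.values()) and all(
        v is not None for v in tsn_pos.values()
    ):
        df["tsn"] = total_shoot_n(df["sdw"], df["n_percent"])
        df["ndfa"] = df["tsn"] - df["genotype"].map(tsn_neg)
        pos = df["genotype"].map(tsn_pos)
        if (pos <= 0).any():
            bad = df.loc[pos <= 0, "genotype"].iloc[0]
            raise DegenerateBaselineError(f"positive-control TSN for {bad!r} must be > 0")
        df["rndfa"] = df["ndfa"] / pos
    return df


@dataclass(frozen=True)
class ScoreMatrix:
    """Strain x genotype matrix of min-max-scaled phenotype scores in [0, 1].

    For binary phenotypes each cell is the proportion of positive plants;
    for continuous ones, cell means rescaled to the observed [min, max].
    Empty cells are NaN (missing, never zero).
    """

    values: pd.DataFrame
    phenotype: str

    def to_csv(self, path: str | Path) -> None:
        self.values.to_csv(path, index_label="strain")


def phenotype_score_matrix(records: pd.DataFrame, phenotype: str) -> ScoreMatrix:
    """Mean per (strain, genotype) cell, min-max scaled to [0, 1].

    ``phenotype`` is one of ``nod``, ``fix`` (binary: the cell value is the
    proportion of positive plants, already on the 0-1 observation scale) or
    ``rsdw`` (continuous: scaled by the observed minimum and maximum cell
    means).  Control rows are excluded.
    """
    binary = {"nod", "fix"}
    if phenotype not in binary | {"rsdw"}:
        raise ValueError(f"phenotype must be nod, fix or rsdw, got {phenotype!r}")
    df = inoculated_only(records)
    if phenotype == "rsdw" and "rsdw" not in df.columns:
        df = inoculated_only(add_derived_responses(records))
    mat = df.pivot_table(
        index="treatment", columns="genotype", values=phenotype, aggfunc="mean"
    )
    # preserve first-appearance order of labels
    mat = mat.reindex(
        index=pd.unique(df["treatment"]), columns=pd.unique(df["genotype"])
    )
    mat.index.name = "strain"
    if phenotype not in binary:
        lo, hi = np.nanmin(mat.values), np.nanmax(mat.values)
        if hi > lo:
            mat = (mat - lo) / (hi - lo)
        else:
            mat = mat * 0.0
    return ScoreMatrix(values=mat, phenotype=phenotype)
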