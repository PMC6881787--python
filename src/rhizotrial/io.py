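"""Reading, validating and writing long-format trial tables.

The canonical on-disk format is a UTF-8 CSV with one row per experimental
unit (plant) and lower-snake headers::

    experiment,genotype,treatment,replicate,nod,fix,nodule_number,nodule_dw,sdw,n_percent

``treatment`` is a strain label or one of ``positive_control`` /
``negative_control``.  ``nod`` and ``fix`` are 0/1 phenotype scores (nodule
formation; pink, leghaemoglobin-containing nodule interiors).  ``n_percent``
(shoot nitrogen concentration) is optional and typically present only for
pot experiments; missing values are explicit NaN, never imputed.  Unknown
extra columns are preserved but ignored by the analysis stages.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

from .design import CONTROL_TREATMENTS, NEGATIVE_CONTROL, TrialDesign

__all__ = [
    "PlantRecord",
    "SchemaError",
    "ValidationError",
    "REQUIRED_COLUMNS",
    "KEY_COLUMNS",
    "records_to_frame",
    "iter_records",
    "validate_trial_frame",
    "read_trial_table",
    "write_trial_table",
    "read_genotype_metadata",
    "inoculated_only",
]


class SchemaError(ValueError):
    """A table is missing required columns or has malformed headers."""


class ValidationError(ValueError):
    """A row violates a plant-record invariant; message names row and rule."""


REQUIRED_COLUMNS = (
    "experiment",
    "genotype",
    "treatment",
    "replicate",
    "nod",
    "fix",
    "nodule_number",
    "nodule_dw",
    "sdw",
)
#: n_percent is part of the canonical schema but may be absent (jar data).
OPTIONAL_COLUMNS = ("n_percent",)
KEY_COLUMNS = ("experiment", "genotype", "treatment", "replicate")


@dataclass(frozen=True)
class PlantRecord:
    """One experimental unit: factor levels plus measured phenotypes."""

    experiment: str
    genotype: str
    treatment: str
    replicate: int
    nod: int
    fix: int
    nodule_number: int
    nodule_dw: float
    sdw: float
    n_percent: Optional[float] = None

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValidationError("replicate must be >= 1")
        if self.nod not in (0, 1) or self.fix not in (0, 1):
            raise ValidationError("nod and fix must be 0 or 1")
        if self.nod == 0 and self.fix != 0:
            raise ValidationError("nod=0 implies fix=0")
        if self.nod == 0 and self.nodule_number != 0:
            raise ValidationError("nod=0 implies nodule_number=0")
        if self.nodule_number < 0:
            raise ValidationError("nodule_number must be >= 0")
        if self.nodule_dw < 0 or self.sdw < 0:
            raise ValidationError("nodule_dw and sdw must be >= 0")
        if self.n_percent is not None and not np.isnan(self.n_percent):
            if not 0.0 <= self.n_percent <= 100.0:
                raise ValidationError("n_percent must lie in [0, 100]")


def records_to_frame(records: Iterable[PlantRecord]) -> pd.DataFrame:
    """Stack plant records into the canonical long-format DataFrame."""
    df = pd.DataFrame([asdict(r) for r in records])
    if df.empty:
        df = pd.DataFrame(columns=list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS))
    return df


def iter_records(df: pd.DataFrame) -> Iterator[PlantRecord]:
    """Yield validated PlantRecord objects from a canonical DataFrame."""
    for row in df.itertuples(index=False):
        n_pct = getattr(row, "n_percent", None)
        if n_pct is not None and pd.isna(n_pct):
            n_pct = None
        yield PlantRecord(
            experiment=str(row.experiment),
            genotype=str(row.genotype),
            treatment=str(row.treatment),
            replicate=int(row.replicate),
            nod=int(row.nod),
            fix=int(row.fix),
            nodule_number=int(row.nodule_number),
            nodule_dw=float(row.nodule_dw),
            sdw=float(row.sdw),
            n_percent=n_pct if n_pct is None else float(n_pct),
        )


def _fail(idx: object, rule: str) -> None:
    raise ValidationError(f"row {idx}: {rule}")


def validate_trial_frame(
    df: pd.DataFrame, design: Optional[TrialDesign] = None
) -> pd.DataFrame:
    """Validate a long-format trial table against the record invariants.

    Returns the frame with canonical dtypes.  With a ``design``, factor
    labels and replicate numbers must additionally fall inside the design.

    Raises
    ------
    SchemaError
        If a required column is missing.
    ValidationError
        Naming the first offending row and the violated rule.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    df = df.copy()
    if "n_percent" not in df.columns:
        df["n_percent"] = np.nan

    for col in ("replicate", "nod", "fix", "nodule_number"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            _fail(df.index[vals.isna()][0], f"{col} is not numeric")
        if (vals != vals.round()).any():
            _fail(df.index[vals != vals.round()][0], f"{col} must be an integer")
        df[col] = vals.astype(int)
    for col in ("nodule_dw", "sdw", "n_percent"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    dup = df.duplicated(subset=list(KEY_COLUMNS), keep=False)
    if dup.any():
        key = tuple(df.loc[df.index[dup][0], list(KEY_COLUMNS)])
        raise ValidationError(f"duplicate unit key {key}")

    checks = [
        (df["replicate"] < 1, "replicate must be >= 1"),
        (~df["nod"].isin((0, 1)), "nod must be 0 or 1"),
        (~df["fix"].isin((0, 1)), "fix must be 0 or 1"),
        ((df["nod"] == 0) & (df["fix"] != 0), "nod=0 implies fix=0"),
        ((df["nod"] == 0) & (df["nodule_number"] != 0), "nod=0 implies nodule_number=0"),
        (df["nodule_number"] < 0, "nodule_number must be >= 0"),
        (df["nodule_dw"].isna() | (df["nodule_dw"] < 0), "nodule_dw must be >= 0"),
        (df["sdw"].isna() | (df["sdw"] < 0), "sdw must be >= 0"),
        (
            df["n_percent"].notna()
            & ((df["n_percent"] < 0) | (df["n_percent"] > 100)),
            "n_percent must lie in [0, 100]",
        ),
    ]
    if design is not None:
        strains = set(design.strains)
        valid_treat = strains | set(CONTROL_TREATMENTS)
        checks += [
            (~df["genotype"].isin(design.genotypes), "genotype not in design"),
            (~df["treatment"].isin(valid_treat), "treatment not in design"),
            (df["replicate"] > design.replicates, "replicate exceeds design"),
        ]
    for mask, rule in checks:
        if mask.any():
            _fail(df.index[mask][0], rule)
    return df


def read_trial_table(
    path: str | Path, design: Optional[TrialDesign] = None
) -> pd.DataFrame:
    """Read and validate a long-format trial CSV."""
    df = pd.read_csv(path)
    return validate_trial_frame(df, design=design)


def write_trial_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table as canonical CSV (validates first)."""
    df = validate_trial_frame(df)
    cols = [c for c in list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS) if c in df.columns]
    extra = [c for c in df.columns if c not in cols]
    df[cols + extra].to_csv(path, index=False)


def read_genotype_metadata(path: str | Path) -> pd.DataFrame:
    """Read the genotype metadata CSV (genepool, growth habit, origin)."""
    df = pd.read_csv(path)
    missing = [c for c in ("genotype", "genepool", "growth_habit", "origin") if c not in df.columns]
    if missing:
        raise SchemaError(f"metadata missing column(s): {', '.join(missing)}")
    if df["genotype"].duplicated().any():
        raise ValidationError("duplicate genotype in metadata")
    return df


def inoculated_only(df: pd.DataFrame) -> pd.DataFrame:
    """Drop control rows, keeping strain-inoculated units."""
    return df[~df["treatment"].isin(CONTROL_TREATMENTS)].copy()
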