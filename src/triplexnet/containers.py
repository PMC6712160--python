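"""Core data containers: expression matrices and clinical tables.

The whole pipeline moves two tabular objects around: a transcripts-by-samples
expression matrix whose rows carry a biotype label (mRNA, lncRNA or miRNA),
and a per-sample clinical table with overall survival and tumour stage.  Both
are thin wrappers over :class:`pandas.DataFrame` with validation and plain-TSV
round-tripping, so every stage of the analysis can be driven from files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BIOTYPES = ("mRNA", "lncRNA", "miRNA")

#: stage labels recognised in clinical tables; anything else (or NaN) is "missing"
STAGES = ("II", "III", "IV")


class ValidationError(ValueError):
    """Raised when a container violates its structural invariants."""


@dataclass
class ExpressionMatrix:
    """Transcripts x samples matrix of non-negative expression values (RPKM
    on input; log2 units after preprocessing) plus a per-transcript biotype.

    Parameters
    ----------
    values
        DataFrame indexed by transcript id, columns are sample ids.
    biotypes
        Series mapping transcript id -> biotype in ``{"mRNA","lncRNA","miRNA"}``,
        index-aligned with ``values``.
    """

    values: pd.DataFrame
    biotypes: pd.Series

    def __post_init__(self) -> None:
        self.biotypes = self.biotypes.reindex(self.values.index)
        self.validate()

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate transcript ids")
        if self.values.columns.has_duplicates:
            raise ValidationError("duplicate sample ids")
        if self.biotypes.isna().any():
            missing = self.biotypes.index[self.biotypes.isna()][:5].tolist()
            raise ValidationError(f"transcripts without biotype label: {missing}")
        bad = set(self.biotypes.unique()) - set(BIOTYPES)
        if bad:
            raise ValidationError(f"unknown biotypes {sorted(bad)}; expected {BIOTYPES}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            raise ValidationError("expression values must be finite")

    # -- convenience --------------------------------------------------------

    @property
    def transcript_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_transcripts(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def biotype_counts(self) -> dict[str, int]:
        counts = self.biotypes.value_counts()
        return {bt: int(counts.get(bt, 0)) for bt in BIOTYPES}

    def subset(self, transcript_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = pd.Index(transcript_ids)
        return ExpressionMatrix(self.values.loc[ids], self.biotypes.loc[ids])

    def row(self, transcript_id: str) -> pd.Series:
        return self.values.loc[transcript_id]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.biotypes.copy())

    # -- I/O -----------------------------------------------------------------

    def to_tsv(self, expr_path: str | Path, anno_path: str | Path) -> None:
        """Write the matrix (first column ``transcript_id``) and the
        annotation table (``transcript_id``, ``biotype``) as TSV."""
        out = self.values.copy()
        out.index.name = "transcript_id"
        out.to_csv(expr_path, sep="\t")
        anno = self.biotypes.rename("biotype").to_frame()
        anno.index.name = "transcript_id"
        anno.to_csv(anno_path, sep="\t")

    @classmethod
    def from_tsv(cls, expr_path: str | Path, anno_path: str | Path) -> "ExpressionMatrix":
        values = pd.read_csv(expr_path, sep="\t", index_col=0)
        anno = pd.read_csv(anno_path, sep="\t", index_col=0)
        if "biotype" not in anno.columns:
            raise ValidationError(f"{anno_path}: annotation table needs a 'biotype' column")
        return cls(values, anno["biotype"])


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations: overall survival (months), the event
    indicator (1 = death observed, 0 = censored) and tumour stage.

    ``stage`` holds labels from ``{"II","III","IV"}``; missing stage is NaN.
    """

    df: pd.DataFrame = field(repr=False)

    REQUIRED = ("os_months", "event", "stage")

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.df.empty:
            raise ValidationError("clinical table is empty")
        for col in self.REQUIRED:
            if col not in self.df.columns:
                raise ValidationError(f"clinical table missing column '{col}'")
        if self.df.index.has_duplicates:
            raise ValidationError("duplicate sample ids in clinical table")
        t = self.df["os_months"].to_numpy(dtype=float)
        if np.nanmin(t) < 0:
            raise ValidationError("os_months must be non-negative")
        ev = self.df["event"].dropna().unique()
        if not set(ev) <= {0, 1}:
            raise ValidationError("event must be 0/1")
        labels = self.df["stage"].dropna().unique()
        bad = set(labels) - set(STAGES)
        if bad:
            raise ValidationError(f"unknown stage labels {sorted(bad)}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.df.index

    def aligned(self, sample_ids: Sequence[str]) -> "ClinicalTable":
        """Restrict to (and order by) the given samples."""
        ids = pd.Index(sample_ids).intersection(self.df.index)
        return ClinicalTable(self.df.loc[ids])

    def to_tsv(self, path: str | Path) -> None:
        out = self.df.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ClinicalTable":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={"stage": "string"})
        df["stage"] = df["stage"].astype(object).where(df["stage"].notna(), np.nan)
        return cls(df)


def stage_ordinal(stage: Optional[str]) -> Optional[int]:
    """Ordinal step of a stage label (II -> 0, III -> 1, IV -> 2); None if missing."""
    try:
        return STAGES.index(stage)  # type: ignore[arg-type]
    except (ValueError, TypeError):
        return None
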