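"""Expression-matrix container shared by every pipeline stage.

The matrix is genes x samples; per-sample metadata carries the condition
(tumor/normal) and batch labels that the normalization, batch-adjustment
and differential-expression stages consume.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

RAW_COUNTS = "raw_counts"
LOG_NORMALIZED = "log_normalized"
BATCH_ADJUSTED = "batch_adjusted"

SCALES = (RAW_COUNTS, LOG_NORMALIZED, BATCH_ADJUSTED)
LOG_SCALES = (LOG_NORMALIZED, BATCH_ADJUSTED)


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix plus sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns.
    sample_meta
        DataFrame indexed by sample id with at least ``condition`` and
        ``batch`` columns; must cover every sample in ``values``.
    scale
        One of ``raw_counts``, ``log_normalized``, ``batch_adjusted``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    scale: str = RAW_COUNTS

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}")
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate gene ids")
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate sample ids")
        if self.sample_meta.index.duplicated().any():
            raise ValidationError("duplicate sample ids in metadata")
        for col in ("condition", "batch"):
            if col not in self.sample_meta.columns:
                raise ValidationError(f"sample sheet lacks column {col!r}")
        missing = [s for s in self.values.columns if s not in self.sample_meta.index]
        if missing:
            raise ValidationError(f"samples missing from metadata: {missing[:5]}")
        # align metadata to the column order of the matrix
        self.sample_meta = self.sample_meta.loc[list(self.values.columns)]
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not np.all(np.isfinite(arr)):
            raise ValidationError("non-finite expression values")
        if self.scale == RAW_COUNTS:
            if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
                raise ValidationError("raw counts must be non-negative integers")

    # -- accessors ---------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def condition_mask(self, condition: str) -> np.ndarray:
        return (self.sample_meta["condition"] == condition).to_numpy()

    def batch_labels(self) -> pd.Series:
        return self.sample_meta["batch"].astype(str)

    # -- derivation --------------------------------------------------------
    def with_values(self, values: pd.DataFrame, scale: str) -> "ExpressionMatrix":
        return ExpressionMatrix(values, self.sample_meta.copy(), scale)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.values.index]
        return replace(self, values=self.values.loc[genes].copy(),
                       sample_meta=self.sample_meta.copy())

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.sample_meta.copy(), self.scale)

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_tsv(cls, counts_path, samples_path, scale: str = RAW_COUNTS) -> "ExpressionMatrix":
        """Read a counts TSV (first column = gene id) and a sample sheet."""
        values = pd.read_csv(counts_path, sep="\t", index_col=0)
        values.index.name = None
        meta = pd.read_csv(samples_path, sep="\t")
        if "sample" not in meta.columns:
            raise FormatError("sample sheet must have a 'sample' column")
        meta = meta.set_index("sample")
        return cls(values, meta, scale)

    def to_tsv(self, counts_path, samples_path=None) -> None:
        out = self.values.copy()
        out.index.name = "gene"
        out.to_csv(counts_path, sep="\t")
        if samples_path is not None:
            meta = self.sample_meta.copy()
            meta.index.name = "sample"
            meta.to_csv(samples_path, sep="\t")


def read_gene_list(path) -> list[str]:
    """Read a plain-text gene list, one id per line, ignoring blanks."""
    text = Path(path).read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]
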