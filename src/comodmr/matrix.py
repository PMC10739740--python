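"""Core expression containers.

The pipeline's central object is a gene × sample matrix that moves through
four layers: raw counts → depth-normalised → log-transformed → covariate
residuals.  The layer tag is carried along so downstream stages can refuse
inputs at the wrong stage (e.g. network construction on raw counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LAYERS = ("raw", "normalised", "transformed", "residualised")

#: columns every sample table must provide (cell-proportion columns are appended later)
SAMPLE_COLUMNS = ("phenotype", "sex", "batch", "pcr_cycles")


@dataclass
class ExpressionMatrix:
    """Gene × sample expression values with a processing-layer tag.

    Parameters
    ----------
    values
        DataFrame with gene ids as the index and sample ids as columns.
    layer
        One of ``raw``, ``normalised``, ``transformed``, ``residualised``.
        The raw layer must hold non-negative integer counts.
    """

    values: pd.DataFrame
    layer: str = "raw"

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if not isinstance(self.values, pd.DataFrame):
            raise TypeError("values must be a pandas DataFrame (genes × samples)")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.layer == "raw":
            arr = self.values.to_numpy()
            if (arr < 0).any():
                raise ValueError("raw counts must be non-negative")
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("raw counts must be integer-valued")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: pd.DataFrame, layer: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(values, layer if layer is not None else self.layer)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return self.with_values(self.values.loc[genes])

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return self.with_values(self.values[list(samples)])


def validate_sample_table(samples: pd.DataFrame, expr: ExpressionMatrix | None = None) -> pd.DataFrame:
    """Check a sample metadata table: required columns, binary phenotype,
    one row per expression sample (when an expression matrix is given)."""
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"sample table missing columns: {missing}")
    pheno = samples["phenotype"]
    if not set(pd.unique(pheno)) <= {0, 1}:
        raise ValueError("phenotype must be binary 0/1 (1 = case)")
    if samples.index.has_duplicates:
        raise ValueError("duplicate sample ids in sample table")
    if expr is not None:
        if set(expr.sample_ids) - set(samples.index):
            raise ValueError("expression samples missing from sample table")
    return samples
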