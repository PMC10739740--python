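"""Count filtering, normalisation, outlier detection, variable-gene
selection and covariate residualisation.

The transformation is depth normalisation by median-of-ratios size factors
followed by log2(x + 1).  The parametric variance-stabilising transform used
on real data is deliberately not reimplemented: every downstream stage works
on correlations, which are insensitive to the exact monotone transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .matrix import ExpressionMatrix


@dataclass
class QCConfig:
    min_count: int = 5
    min_samples: int = 10
    top_expressed_for_outliers: int = 100
    variable_gene_quantile: float = 0.75
    outlier_height_factor: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 < self.variable_gene_quantile < 1.0:
            raise ValueError("variable_gene_quantile must be in (0, 1)")
        if self.outlier_height_factor <= 0:
            raise ValueError("outlier_height_factor must be positive")


def filter_genes(raw: ExpressionMatrix, cfg: QCConfig = QCConfig()) -> ExpressionMatrix:
    """Keep genes with >= ``min_count`` counts in >= ``min_samples`` samples."""
    if raw.layer != "raw":
        raise ValueError("filter_genes expects the raw count layer")
    keep = (raw.values >= cfg.min_count).sum(axis=1) >= cfg.min_samples
    if not keep.any():
        raise ValueError("gene filter removed every gene")
    return raw.with_values(raw.values.loc[keep])


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors over all-positive genes.

    Falls back to library size over its geometric mean when no gene is
    positive in every sample.
    """
    arr = counts.to_numpy(dtype=float)
    if (arr.sum(axis=0) == 0).any():
        raise ValueError("sample with zero total count")
    positive = (arr > 0).all(axis=1)
    if positive.any():
        logs = np.log(arr[positive])
        ref = logs.mean(axis=1, keepdims=True)  # log geometric mean per gene
        log_sf = np.median(logs - ref, axis=0)
    else:
        lib = arr.sum(axis=0)
        log_sf = np.log(lib)
    # size factors are defined up to scale; fix geometric mean to 1
    sf = np.exp(log_sf - log_sf.mean())
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalise_transform(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Depth-normalise by size factors, then log2(x + 1)."""
    if counts.layer != "raw":
        raise ValueError("normalise_transform expects the raw count layer")
    sf = size_factors(counts.values)
    norm = counts.values / sf
    return counts.with_values(np.log2(norm + 1.0), layer="transformed")


def _leaf_merge_heights(Z: np.ndarray, n: int) -> np.ndarray:
    """Height at which each of the n leaves first joins a cluster."""
    h = np.full(n, np.nan)
    for a, b, height, _ in Z:
        for node in (int(a), int(b)):
            if node < n:
                h[node] = height
    return h


def detect_outlier_samples(x: ExpressionMatrix, cfg: QCConfig = QCConfig()) -> list[str]:
    """Flag samples by hierarchical clustering of the top expressed genes.

    Average-linkage Euclidean clustering on the ``top_expressed_for_outliers``
    genes by mean expression; a sample is flagged when the height at which it
    first merges exceeds mean + ``outlier_height_factor`` · sd of all merge
    heights.  Flagged samples are reported, never dropped.
    """
    if x.layer not in ("transformed", "normalised", "residualised"):
        raise ValueError("detect_outlier_samples expects transformed values")
    if x.n_samples < 3:
        raise ValueError("need at least 3 samples for outlier detection")
    top = x.values.mean(axis=1).nlargest(cfg.top_expressed_for_outliers).index
    mat = x.values.loc[top].to_numpy().T  # samples × genes
    Z = linkage(pdist(mat), method="average")
    heights = Z[:, 2]
    cut = heights.mean() + cfg.outlier_height_factor * heights.std(ddof=0)
    leaf_h = _leaf_merge_heights(Z, x.n_samples)
    return [s for s, h in zip(x.sample_ids, leaf_h) if h > cut]


def select_variable_genes(x: ExpressionMatrix, cfg: QCConfig = QCConfig()) -> ExpressionMatrix:
    """Keep the top ``variable_gene_quantile`` fraction of genes by variance.

    The retained count is ceil(q · G); ties are broken by gene id order so
    the result is deterministic.
    """
    q = cfg.variable_gene_quantile
    n_keep = int(np.ceil(q * x.n_genes))
    var = x.values.var(axis=1, ddof=1)
    # stable sort: variance descending, gene id ascending on ties
    ranked = var.sort_index(kind="mergesort").sort_values(ascending=False, kind="mergesort")
    keep = set(ranked.index[:n_keep])
    return x.subset_genes([g for g in x.gene_ids if g in keep])


def build_design(samples: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Intercept + covariates; categoricals one-hot encoded, first level dropped."""
    cols = {"intercept": np.ones(len(samples))}
    for c in covariates:
        col = samples[c]
        if col.dtype.kind in "OUb" or c == "batch":
            dummies = pd.get_dummies(col.astype("category"), prefix=c, drop_first=True, dtype=float)
            for d in dummies:
                cols[d] = dummies[d].to_numpy()
        else:
            cols[c] = col.to_numpy(dtype=float)
    return pd.DataFrame(cols, index=samples.index)


def residualise(
    x: ExpressionMatrix, samples: pd.DataFrame, covariates: list[str]
) -> ExpressionMatrix:
    """Per-gene OLS residuals against the covariate design, intercept added back.

    Raises on a rank-deficient design, naming the collinear columns.
    """
    design = build_design(samples.loc[x.sample_ids], covariates)
    D = design.to_numpy()
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        # identify columns whose removal restores full rank
        collinear = [
            c
            for i, c in enumerate(design.columns)
            if np.linalg.matrix_rank(np.delete(D, i, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient covariate design; collinear columns: {collinear}")
    Y = x.values.to_numpy().T  # samples × genes
    beta, *_ = np.linalg.lstsq(D, Y, rcond=None)
    resid = Y - D @ beta
    fitted_intercept = np.outer(np.ones(len(design)), beta[0])
    out = (resid + fitted_intercept).T
    return x.with_values(
        pd.DataFrame(out, index=x.gene_ids, columns=x.sample_ids), layer="residualised"
    )
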