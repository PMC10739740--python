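"""Cell-type proportion estimation from bulk counts via a labelled
single-cell reference.

Proportions are obtained by non-negative least squares of bulk CPM on the
per-type signature columns, renormalised to sum to one.  The proportions
serve only as covariates downstream, so a fully specified linear estimator
is preferred over reference-based moment matching; ``rescale_bulk=True``
enables an optional per-gene moment-matching mode (bulk rescaled to the
reference's per-gene mean/sd before the fit).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .matrix import ExpressionMatrix


class DegenerateSignatureWarning(UserWarning):
    """Signature columns are collinear (or a sample fit returned all zeros)."""


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("sample/cell with zero total count")
    return counts * 1e6 / lib


def build_signature(
    reference_counts: pd.DataFrame, labels: pd.Series, bulk_genes=None
) -> pd.DataFrame:
    """Per-type mean CPM signature, restricted to genes present in the bulk."""
    labels = labels.loc[reference_counts.columns]
    ref_cpm = cpm(reference_counts)
    sig = ref_cpm.T.groupby(labels).mean().T
    if bulk_genes is not None:
        sig = sig.loc[sig.index.intersection(pd.Index(bulk_genes))]
    if sig.shape[1] < 2:
        raise ValueError("need at least 2 cell types in the signature")
    return sig


def estimate_proportions(
    bulk: ExpressionMatrix, signature: pd.DataFrame, rescale_bulk: bool = False, min_shared: int = 50
) -> pd.DataFrame:
    """NNLS proportions per bulk sample (rows sum to 1).

    A sample whose NNLS coefficients are all zero gets uniform proportions
    with a warning.  Collinear signature columns are flagged degenerate.
    """
    shared = bulk.gene_ids.intersection(signature.index)
    if len(shared) < min_shared:
        raise ValueError(f"only {len(shared)} shared genes between bulk and signature (< {min_shared})")
    S = signature.loc[shared].to_numpy(dtype=float)
    if np.linalg.matrix_rank(S) < S.shape[1]:
        warnings.warn(
            "signature columns are collinear; proportions are not identifiable",
            DegenerateSignatureWarning,
        )
    bulk_vals = bulk.values.loc[shared]
    if bulk.layer == "raw":
        bulk_vals = cpm(bulk_vals)
    if rescale_bulk:
        # moment matching: put each bulk gene on the reference's per-gene scale
        ref_mean = S.mean(axis=1)
        ref_sd = S.std(axis=1) + 1e-12
        b_mean = bulk_vals.mean(axis=1).to_numpy()
        b_sd = bulk_vals.std(axis=1).to_numpy() + 1e-12
        bulk_vals = (
            (bulk_vals.sub(b_mean, axis=0)).div(b_sd, axis=0).mul(ref_sd, axis=0).add(ref_mean, axis=0)
        ).clip(lower=0)
    rows = {}
    for s in bulk.sample_ids:
        coef, _ = nnls(S, bulk_vals[s].to_numpy(dtype=float))
        total = coef.sum()
        if total == 0:
            warnings.warn(f"all-zero NNLS fit for sample {s}; using uniform proportions", DegenerateSignatureWarning)
            coef = np.ones(S.shape[1])
            total = coef.sum()
        rows[s] = coef / total
    return pd.DataFrame(rows, index=signature.columns).T.rename_axis("sample")


def select_proportion_covariates(proportions: pd.DataFrame, threshold: float = 0.05) -> list[str]:
    """Cell types whose mean proportion is strictly above the threshold."""
    means = proportions.mean(axis=0)
    return [ct for ct in proportions.columns if means[ct] > threshold]


def attach_proportions(samples: pd.DataFrame, proportions: pd.DataFrame, threshold: float = 0.05) -> tuple[pd.DataFrame, list[str]]:
    """Append selected proportion columns to the sample table; returns (table, columns).

    When every cell type passes the threshold the columns sum to one and are
    collinear with a model intercept, so the smallest-mean type is dropped as
    the reference category.
    """
    keep = select_proportion_covariates(proportions, threshold)
    if len(keep) == proportions.shape[1] and len(keep) > 1:
        keep = keep[:-1] if proportions[keep].mean().idxmin() == keep[-1] else [
            c for c in keep if c != proportions[keep].mean().idxmin()
        ]
    out = samples.join(proportions[keep].add_prefix("prop_"))
    return out, [f"prop_{c}" for c in keep]
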