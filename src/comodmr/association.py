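"""Eigengene–phenotype association and group-comparison tests.

Each module eigengene is tested against case/control status with logistic
regression (Wald z on the eigengene coefficient) adjusting for covariates;
p-values are corrected across modules by Benjamini–Hochberg, with a 20% FDR
default reflecting the exploratory setting of small-effect bulk studies.
Perfect separation is detected and the module flagged non-estimable rather
than reporting divergent estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .preprocess import build_design


@dataclass
class AssociationConfig:
    fdr_level: float = 0.20
    covariates: list[str] = field(default_factory=list)


@dataclass
class AssociationResult:
    module: str
    beta: float
    se: float
    p: float
    q: float = np.nan
    significant: bool = False
    estimable: bool = True


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up: q_(i) = min_{j>=i} p_(j)·m/j, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _fit_logit(y: np.ndarray, X: np.ndarray) -> tuple[float, float, float, bool]:
    """Returns (beta, se, p, estimable) for the second design column."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception:
            return np.nan, np.nan, np.nan, False
    params = np.asarray(fit.params, dtype=float)
    bse = np.asarray(fit.bse, dtype=float)
    fitted = np.asarray(fit.predict(X))
    separated = np.all(np.abs(fitted - y) < 1e-6) or not np.isfinite(bse[1]) or bse[1] > 1e4
    if separated or not np.isfinite(params[1]):
        return np.nan, np.nan, np.nan, False
    z = params[1] / bse[1]
    return float(params[1]), float(bse[1]), float(2 * stats.norm.sf(abs(z))), True


def associate_modules(
    eigengenes: pd.DataFrame,
    samples: pd.DataFrame,
    cfg: AssociationConfig = AssociationConfig(),
) -> pd.DataFrame:
    """Per-module logistic regression of phenotype on eigengene + covariates.

    Returns a DataFrame (module, beta, se, p, q, significant, estimable);
    BH correction runs across the estimable modules.
    """
    pheno = samples["phenotype"]
    if not set(pd.unique(pheno)) <= {0, 1}:
        raise ValueError("phenotype must be binary 0/1")
    y = pheno.loc[eigengenes.index].to_numpy(dtype=float)
    design = build_design(samples.loc[eigengenes.index], cfg.covariates)
    results = []
    for col in eigengenes.columns:
        X = np.column_stack([np.ones(len(y)), eigengenes[col].to_numpy(), design.to_numpy()[:, 1:]])
        beta, se, p, ok = _fit_logit(y, X)
        results.append(AssociationResult(module=col, beta=beta, se=se, p=p, estimable=ok))
    df = pd.DataFrame([r.__dict__ for r in results]).set_index("module")
    mask = df["estimable"] & df["p"].notna()
    if mask.any():
        df.loc[mask, "q"] = bh_fdr(df.loc[mask, "p"].to_numpy())
        df["significant"] = df["q"] < cfg.fdr_level
    return df


def compare_groups(variables: dict) -> pd.DataFrame:
    """Group-comparison tests for a subject-characteristics table.

    Each entry of ``variables`` maps a name to either

    - ``{"type": "categorical", "table": [[a, b], [c, d]]}`` — a 2×2 count
      table (rows = groups).  If any expected cell count is below 5 the
      two-sided Fisher exact test is used, otherwise the Pearson chi-squared
      test without continuity correction.
    - ``{"type": "numeric", "case_values": [...], "control_values": [...]}``
      — two-sided Wilcoxon rank-sum with normal approximation and tie
      correction.
    """
    rows = []
    for name, spec in variables.items():
        if spec["type"] == "categorical":
            t = np.asarray(spec["table"], dtype=float)
            if t.shape != (2, 2):
                raise ValueError(f"{name}: categorical variables need a 2×2 table")
            if (t < 0).any():
                raise ValueError(f"{name}: negative counts")
            expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
            if (expected < 5).any():
                test = "fisher"
                p = stats.fisher_exact(t.astype(int), alternative="two-sided")[1]
            else:
                test = "chi2"
                p = stats.chi2_contingency(t, correction=False)[1]
        elif spec["type"] == "numeric":
            a = np.asarray(spec["case_values"], dtype=float)
            b = np.asarray(spec["control_values"], dtype=float)
            test = "wilcoxon"
            p = stats.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic", use_continuity=False
            )[1]
        else:
            raise ValueError(f"{name}: unknown variable type {spec['type']!r}")
        rows.append({"variable": name, "test": test, "p": float(p)})
    return pd.DataFrame(rows).set_index("variable")
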