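"""Top-gene set construction, PPI channel recombination, hub identification
and the max-degree permutation test.

The "top asthma-gene" set is the union of (a) genes with colocalisation
evidence PP4 ≥ 0.5 and (b) genes in the top decile of both module membership
(within their own module) and absolute gene significance (across the
combined associated-module genes).  The PPI network is re-scored after
excluding the co-expression, neighbourhood and gene-fusion channels — these
duplicate the information the modules were built from — using the standard
evidence-combination rule with prior 0.041, and thresholded at combined
score 0.4.  The hub is the maximum-degree node of the induced subgraph; its
significance is the add-one empirical p of the observed max degree against
max degrees of random same-size gene sets drawn from the combined
associated-module genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import PPI_CHANNELS

DEFAULT_EXCLUSIONS = ("coexpression", "neighbourhood", "fusion")
STRING_PRIOR = 0.041


@dataclass
class TopGeneConfig:
    pp4_threshold: float = 0.5
    mm_quantile: float = 0.90
    gs_quantile: float = 0.90
    channel_exclusions: tuple[str, ...] = DEFAULT_EXCLUSIONS
    combined_score_min: float = 0.4
    n_permutations: int = 10_000
    seed: int = 0
    combine: str = "union"  # or "intersection" of coloc and MM∧GS criteria

    def __post_init__(self) -> None:
        if not (0 < self.mm_quantile < 1 and 0 < self.gs_quantile < 1):
            raise ValueError("quantiles must be in (0, 1)")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")


@dataclass
class HubResult:
    hub: str
    observed_max_degree: int
    degrees: pd.Series
    p: float = np.nan
    perm_max_degrees: np.ndarray | None = None
    tied_hubs: tuple[str, ...] = ()


def combine_channel_scores(scores: np.ndarray, prior: float = STRING_PRIOR) -> np.ndarray:
    """Combined score from per-channel scores (evidence-combination rule).

    Each channel is prior-corrected, the corrected scores are combined as
    independent evidence, and the prior is added back once.
    """
    s = np.clip((np.asarray(scores, dtype=float) - prior) / (1.0 - prior), 0.0, None)
    combined = 1.0 - np.prod(1.0 - s, axis=-1)
    return combined * (1.0 - prior) + prior


def recombine_scores(
    edges: pd.DataFrame,
    exclusions: tuple[str, ...] = DEFAULT_EXCLUSIONS,
    prior: float = STRING_PRIOR,
    combined_score_min: float = 0.4,
) -> pd.DataFrame:
    """Recompute combined scores from the non-excluded channels and drop
    edges below the score threshold."""
    unknown = set(exclusions) - set(PPI_CHANNELS)
    if unknown:
        raise ValueError(f"unknown channels: {sorted(unknown)}")
    keep = [c for c in PPI_CHANNELS if c not in exclusions]
    out = edges.copy()
    out["combined"] = combine_channel_scores(out[keep].to_numpy(), prior) if keep else prior
    return out[out["combined"] >= combined_score_min].reset_index(drop=True)


def build_top_gene_set(
    coloc_results: pd.DataFrame,
    module_set,
    assoc_modules: list[int],
    cfg: TopGeneConfig = TopGeneConfig(),
) -> pd.DataFrame:
    """Top-gene set with provenance tags.

    Criterion 1: PP4 ≥ threshold.  Criterion 2∧3: MM in the top decile of the
    gene's own module AND |GS| in the top decile over the combined
    associated-module genes.  Returns a DataFrame (gene, coloc, mm_gs).
    """
    if not assoc_modules:
        raise ValueError("no phenotype-associated modules")
    labels = module_set.labels
    module_genes = labels.index[labels.isin(assoc_modules)]
    if len(module_genes) == 0:
        raise ValueError("associated modules contain no genes")

    coloc_genes: set[str] = set()
    if coloc_results is not None and len(coloc_results):
        hit = coloc_results[coloc_results["PP4"] >= cfg.pp4_threshold]
        coloc_genes = set(hit["gene"]) & set(module_genes)

    gs = module_set.gene_significance.loc[module_genes].abs()
    gs_cut = gs.quantile(cfg.gs_quantile, interpolation="lower")
    mm_hits: set[str] = set()
    for m in assoc_modules:
        genes = labels.index[labels == m]
        col = f"ME{m}"
        if col not in module_set.membership.columns or len(genes) == 0:
            continue
        mm = module_set.membership.loc[genes, col]
        mm_cut = mm.quantile(cfg.mm_quantile, interpolation="lower")
        mm_hits |= set(mm.index[(mm >= mm_cut)])
    joint = {g for g in mm_hits if gs[g] >= gs_cut}

    selected = coloc_genes | joint if cfg.combine == "union" else coloc_genes & joint
    rows = [
        {"gene": g, "coloc": g in coloc_genes, "mm_gs": g in joint}
        for g in sorted(selected)
    ]
    return pd.DataFrame(rows, columns=["gene", "coloc", "mm_gs"])


def _adjacency(edges: pd.DataFrame, nodes: list[str]) -> np.ndarray:
    idx = {g: i for i, g in enumerate(nodes)}
    A = np.zeros((len(nodes), len(nodes)), dtype=bool)
    for p1, p2 in zip(edges["protein1"], edges["protein2"]):
        i, j = idx.get(p1), idx.get(p2)
        if i is not None and j is not None and i != j:
            A[i, j] = A[j, i] = True
    return A


def hub_statistic(edges: pd.DataFrame, gene_set) -> HubResult:
    """Max-degree node of the subgraph induced on the gene set.

    Ties are broken lexicographically; all tied nodes are reported.
    """
    nodes = sorted(set(gene_set))
    A = _adjacency(edges, nodes)
    deg = A.sum(axis=1).astype(int)
    degrees = pd.Series(deg, index=nodes, name="degree")
    max_deg = int(deg.max()) if len(nodes) else 0
    tied = tuple(degrees.index[degrees == max_deg]) if len(nodes) else ()
    hub = tied[0] if tied else ""
    return HubResult(hub=hub, observed_max_degree=max_deg, degrees=degrees, tied_hubs=tied)


def permutation_test(
    edges: pd.DataFrame,
    universe,
    set_size: int,
    cfg: TopGeneConfig = TopGeneConfig(),
    observed: HubResult | None = None,
) -> HubResult:
    """Add-one empirical p of the observed max degree.

    Draws ``n_permutations`` same-size gene sets without replacement from the
    combined associated-module gene universe; the statistic is the maximum
    induced degree; p = (1 + #{stat ≥ observed}) / (1 + B).
    """
    universe = sorted(set(universe))
    if set_size > len(universe):
        raise ValueError("set size exceeds universe")
    A = _adjacency(edges, universe)
    rng = np.random.default_rng(cfg.seed)
    B = cfg.n_permutations
    stats = np.empty(B, dtype=int)
    n = len(universe)
    for b in range(B):
        idx = rng.choice(n, set_size, replace=False)
        sub = A[np.ix_(idx, idx)]
        stats[b] = int(sub.sum(axis=1).max()) if set_size else 0
    if observed is None:
        raise ValueError("observed HubResult required")
    p = (1 + int((stats >= observed.observed_max_degree).sum())) / (1 + B)
    return HubResult(
        hub=observed.hub,
        observed_max_degree=observed.observed_max_degree,
        degrees=observed.degrees,
        p=p,
        perm_max_degrees=stats,
        tied_hubs=observed.tied_hubs,
    )


def identify_master_regulator(
    edges: pd.DataFrame,
    top_genes: pd.DataFrame,
    module_universe,
    cfg: TopGeneConfig = TopGeneConfig(),
) -> HubResult:
    """Recombine channels, induce the top-gene subgraph, test the hub."""
    pruned = recombine_scores(
        edges, cfg.channel_exclusions, combined_score_min=cfg.combined_score_min
    )
    obs = hub_statistic(pruned, top_genes["gene"])
    return permutation_test(pruned, module_universe, len(top_genes), cfg, observed=obs)
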