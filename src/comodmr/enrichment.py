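"""Over-representation analysis of module genes in GMT gene-set collections.

One-sided hypergeometric (Fisher) test per set: with a universe of U genes,
a set covering N of them and a module of M universe genes overlapping n,
p = P(X >= n) for X ~ Hypergeometric(U, N, M).  BH correction runs across
the sets of a collection.  The default universe is the post-filter network
gene list; genome-wide universes give systematically smaller p-values and
can be supplied instead.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from .io import read_gmt, write_gmt  # noqa: F401  (re-exported collection I/O)


def ora_fisher(module_genes, collection: dict[str, list[str]], universe) -> pd.DataFrame:
    """Enrichment of a module in every set of a GMT collection.

    Returns a DataFrame sorted by (q, set name) with columns
    set, N, n, p, q, gene_ratio, genes.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    module = set(module_genes) & universe
    rows = []
    for name, genes in collection.items():
        gene_set = set(genes) & universe
        if not gene_set:
            continue
        overlap = sorted(gene_set & module)
        n = len(overlap)
        p = stats.hypergeom.sf(n - 1, len(universe), len(gene_set), len(module))
        rows.append(
            {
                "set": name,
                "N": len(gene_set),
                "n": n,
                "p": float(p),
                "gene_ratio": n / len(module) if module else 0.0,
                "genes": ",".join(overlap),
            }
        )
    df = pd.DataFrame(rows, columns=["set", "N", "n", "p", "gene_ratio", "genes"])
    if not df.empty:
        from .association import bh_fdr

        df["q"] = bh_fdr(df["p"].to_numpy())
        df = df.sort_values(["q", "set"], kind="mergesort").reset_index(drop=True)
    else:
        df["q"] = []
    return df[["set", "N", "n", "p", "q", "gene_ratio", "genes"]]


def write_enrichment(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False)
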