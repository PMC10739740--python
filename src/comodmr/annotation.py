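"""SNP-to-gene annotation of GWAS lead signals.

Leads are first expanded with LD proxies at r² ≥ 0.7, then each SNP is
annotated to protein-coding genes by three independent rules:

1. the SNP position falls inside a gene body (0-based half-open);
2. the nearest gene ending before the position and the nearest gene starting
   after it (distance from gene-body boundaries; both neighbours kept);
3. the SNP falls in the other end of a promoter-capture interaction whose
   bait is a gene promoter.

The tagged union of the three rules is reported, then intersected with the
phenotype-associated module genes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def expand_proxies(lead_snps, ld, r2_threshold: float = 0.7) -> set[str]:
    """Leads plus every SNP with r² ≥ threshold to any lead.

    ``ld`` is either a square signed-correlation DataFrame (snp × snp) or a
    long proxy table with columns (lead, proxy, r2).
    """
    leads = set(lead_snps)
    out = set(leads)
    if ld is None or len(ld) == 0:
        return out
    if isinstance(ld, pd.DataFrame) and {"lead", "proxy", "r2"} <= set(ld.columns):
        hits = ld[(ld["lead"].isin(leads)) & (ld["r2"] >= r2_threshold)]
        out |= set(hits["proxy"])
    else:
        for lead in leads & set(ld.index):
            r2 = ld.loc[lead] ** 2
            out |= set(r2.index[r2 >= r2_threshold])
    return out


def annotate_snp(chrom: str, pos: int, gene_models: pd.DataFrame, interactions: pd.DataFrame | None = None) -> pd.DataFrame:
    """Genes annotated to one SNP position with per-rule tags.

    Returns a DataFrame (gene, rules) where rules is a comma-joined subset of
    {body, nearest, interaction}.
    """
    models = gene_models[gene_models["chr"] == chrom]
    tags: dict[str, set[str]] = {}
    if models.empty:
        warnings.warn(f"no gene models on chromosome {chrom}")
    else:
        inside = models[(models["start"] <= pos) & (pos < models["end"])]
        for g in inside["gene"]:
            tags.setdefault(g, set()).add("body")
        before = models[models["end"] <= pos]
        if len(before):
            nearest = before.loc[(pos - before["end"]).idxmin(), "gene"]
            tags.setdefault(nearest, set()).add("nearest")
        after = models[models["start"] > pos]
        if len(after):
            nearest = after.loc[(after["start"] - pos).idxmin(), "gene"]
            tags.setdefault(nearest, set()).add("nearest")
    if interactions is not None and len(interactions):
        hit = interactions[
            (interactions["chr2"] == chrom)
            & (interactions["start2"] <= pos)
            & (pos < interactions["end2"])
        ]
        for g in hit["gene"]:
            tags.setdefault(g, set()).add("interaction")
    rows = [{"gene": g, "rules": ",".join(sorted(r))} for g, r in sorted(tags.items())]
    return pd.DataFrame(rows, columns=["gene", "rules"])


def annotate_snps(
    snps: pd.DataFrame, gene_models: pd.DataFrame, interactions: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Annotate a (snp, chr, pos) table; one row per (snp, gene, rules)."""
    out = []
    for _, row in snps.iterrows():
        ann = annotate_snp(str(row["chr"]), int(row["pos"]), gene_models, interactions)
        ann.insert(0, "snp", row["snp"])
        out.append(ann)
    if not out:
        return pd.DataFrame(columns=["snp", "gene", "rules"])
    return pd.concat(out, ignore_index=True)


def filter_to_modules(annotations: pd.DataFrame, module_genes) -> pd.DataFrame:
    """Keep annotations whose gene belongs to the associated modules."""
    keep = set(module_genes)
    return annotations[annotations["gene"].isin(keep)].reset_index(drop=True)
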