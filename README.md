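# comodmr

Co-expression **mod**ules and **m**aster-**r**egulator inference for bulk
CD4⁺ T-cell transcriptomics.

Bulk RNA-seq studies of well-controlled asthma typically find no individual
differentially expressed genes: the case/control differences are small and
spread across co-regulated gene programmes. `comodmr` implements the
network-level inference chain used in that setting, from a raw gene × sample
count matrix to a genetically supported "master regulator" call:

1. **QC** — count filtering (≥5 counts in ≥10 samples), depth normalisation
   (median-of-ratios size factors) with log2 transform, hierarchical-cluster
   outlier flagging on the top-100 expressed genes, top-75% variable-gene
   selection.
2. **Deconvolution covariates** — CD4⁺ sub-population proportions by NNLS
   against a labelled single-cell signature; cell types with mean
   proportion > 5% become covariates.
3. **Signed-hybrid WGCNA** — adjacency `a_ij = max(cor_ij, 0)^β` (default
   β = 6), topological overlap
   `TOM_ij = (ℓ_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)`, average-linkage
   clustering of `1 − TOM` into modules, module eigengenes (first PC of the
   standardised module block), module membership (kME) and gene significance
   (GS).
4. **Association** — per-module logistic regression
   `logit P(case) = b₀ + b₁·ME + covariates`, Wald test, Benjamini–Hochberg
   FDR at 20%.
5. **Enrichment** — one-sided hypergeometric (Fisher) over-representation of
   module genes in GMT collections.
6. **Colocalisation** — Wakefield approximate Bayes factors
   `log ABF = ½log(1 − r) + z²r/2` with `r = W/(V + W)`, region posteriors
   PP0–PP4, evidence rule PP4 > 0.5.
7. **SNP-to-gene annotation** — LD-proxy expansion at r² ≥ 0.7, then gene
   body overlap, closest preceding/following gene, and promoter-capture
   Hi-C other-end containment.
8. **Master regulator** — top-gene set (PP4 ≥ 0.5 ∪ joint top-decile
   MM ∧ |GS|), STRING-style channel recombination with co-expression,
   neighbourhood and fusion channels excluded, hub = max-degree node of the
   induced PPI subgraph, add-one permutation p against random same-size sets
   from the associated-module genes.

A first-class synthetic-data module generates **every** input (counts,
sample table, single-cell reference, GWAS/eQTL summary statistics with AR(1)
LD, gene models, pcHi-C interactions, PPI edge table, GMT sets) with known
ground truth, so the full pipeline is exercisable and testable offline.

## Worked example

```sh
comodmr run-all --outdir demo_run --seed 0
```

prints the stage summary of a complete synthetic run:

```json
{
 "n_genes_filtered": 1200,
 "n_genes_variable": 900,
 "outlier_samples": [],
 "proportion_covariates": ["prop_CT0", "prop_CT1", "prop_CT2"],
 "n_modules": 2,
 "assoc_modules": [1, 2],
 "n_assoc_genes": 172,
 "n_top_genes": 39,
 "hub": {"hub": "G00018", "observed_max_degree": 30,
         "p": 0.0004997501249375312, "tied_hubs": ["G00018"]}
}
```

Reading: of 1,200 simulated genes, 900 survive variable-gene selection; two
co-expression modules are detected and both associate with case status at
20% FDR (they recover the two planted case-shifted modules); the three cell
types above the 5% rule enter as covariates; the top-gene set of 39 genes
yields hub `G00018` — the planted master regulator, wired to the colocalised
cis genes — with 30 induced edges and permutation p ≈ 5 × 10⁻⁴ at B = 2,000.
Full per-stage tables (modules, eigengenes, association, enrichment, coloc
PP0–PP4, SNP annotation, top genes) are written under `demo_run/results/`,
and `demo_run/manifest.json` records seeds and per-file SHA-256 checksums;
rerunning with the same seed reproduces every byte.

The same stages are available as library functions
(`comodmr.build_network`, `comodmr.coloc_abf`, …) and as individual CLI
subcommands (`comodmr simulate|preprocess|deconvolve|network|associate|
enrich|coloc|annotate|hub`).

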