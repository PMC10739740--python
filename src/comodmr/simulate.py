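"""Synthetic data generators with known ground truth.

Every input the pipeline consumes — bulk counts, sample metadata, a labelled
single-cell reference, GWAS/eQTL summary statistics with LD, a PPI edge
table — can be generated here with the statistical structure the analysis
assumes, so each downstream stage is testable end to end without downloads.

Count model
-----------
Counts are Poisson–lognormal: a latent log-expression
``eta = loading·factor + covariate effects + noise`` is exponentiated and
scaled to the sample's library size before Poisson sampling.  Overdispersion
enters through the lognormal latent, which is sufficient because every
downstream stage works on correlations, not count likelihoods.  Module genes
share a per-sample latent factor; for the first ``n_assoc_modules`` modules
the factor mean is shifted by ``factor_effect`` standard deviations in cases.
The gene–factor loading equals ``within_module_cor``, so the expected latent
pairwise correlation inside a module is its square.

LD model
--------
Genotype correlation is AR(1): ``R[i, j] = ld_decay ** |i - j|``.  Marginal
z-scores follow the standard summary-statistic model
``z ~ MVN(R z_causal, R)``; per-SNP standard errors use the GWAS
approximation ``se = 1 / sqrt(2 N maf (1 - maf))``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

PPI_CHANNELS = (
    "experiments",
    "database",
    "textmining",
    "coexpression",
    "neighbourhood",
    "fusion",
    "cooccurrence",
)

# allele pairs that survive strand checks (no A/T or C/G ambiguity)
_NON_PALINDROMIC = (("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"))
_PALINDROMIC = (("A", "T"), ("C", "G"))


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the emulated study design: 32 cases vs 11 controls,
    ~10⁴ genes with block co-expression, two asthma-associated modules with
    a moderate latent shift, four CD4⁺ sub-populations of which one averages
    below the 5% covariate-selection threshold, 3'-seq-like library sizes
    (~8M reads), and a STRING-like PPI with one planted hub.
    """

    seed: int = 0
    n_cases: int = 32
    n_controls: int = 11
    n_genes: int = 10_000
    module_sizes: tuple[int, ...] = (400, 300, 200, 100)
    n_assoc_modules: int = 2
    factor_effect: float = 1.5
    within_module_cor: float = 0.8
    library_size_lognorm: tuple[float, float] = (15.9, 0.25)
    covariate_effects: dict = field(
        default_factory=lambda: {"sex": 0.15, "batch": 0.15, "pcr_cycles": 0.10}
    )
    bio_sd: float = 0.4
    baseline_sd: float = 1.2
    n_celltypes: int = 4
    dirichlet_alpha: tuple[float, ...] = (10.0, 6.0, 2.0, 0.5)
    cells_per_type: int = 50
    marker_genes_per_type: int = 30
    marker_fold: float = 8.0
    region_n_snps: int = 200
    ld_decay: float = 0.9
    eqtl_beta: float = 0.5
    gwas_beta: float = 0.5
    sumstats_n: int = 10_000
    allele_flip_frac: float = 0.1
    palindromic_frac: float = 0.0
    n_ppi_nodes: int = 500
    ppi_edge_prob: float = 0.05
    hub_extra_degree: int = 30

    def validate(self) -> "SimConfig":
        for name in ("n_cases", "n_controls", "n_genes", "n_celltypes", "n_ppi_nodes", "region_n_snps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if any(s <= 0 for s in self.module_sizes):
            raise ValueError("module sizes must be > 0")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("sum(module_sizes) exceeds n_genes")
        if self.n_assoc_modules > len(self.module_sizes):
            raise ValueError("n_assoc_modules exceeds number of modules")
        if not 0.0 <= self.within_module_cor < 1.0:
            raise ValueError("within_module_cor must be in [0, 1)")
        if not 0.0 <= self.ld_decay < 1.0:
            raise ValueError("ld_decay must be in [0, 1)")
        if len(self.dirichlet_alpha) != self.n_celltypes:
            raise ValueError("dirichlet_alpha length must equal n_celltypes")
        return self


@dataclass
class SimTruth:
    """Ground truth emitted alongside each synthetic dataset."""

    module_label_per_gene: dict = field(default_factory=dict)
    assoc_module_ids: list = field(default_factory=list)
    causal_snps: dict = field(default_factory=dict)
    shared_causal: bool | None = None
    true_proportions: dict = field(default_factory=dict)
    planted_hub_node: str | None = None
    celltype_means: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


def _streams(cfg: SimConfig, *names: str):
    """Deterministic named sub-streams from the single config seed."""
    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def module_labels(cfg: SimConfig) -> np.ndarray:
    """Per-gene module label; 0 = background."""
    lab = np.zeros(cfg.n_genes, dtype=int)
    pos = 0
    for m, size in enumerate(cfg.module_sizes, start=1):
        lab[pos : pos + size] = m
        pos += size
    return lab


def _celltype_means(cfg: SimConfig) -> np.ndarray:
    """Per-cell-type mean expression profiles (genes × types), column-normalised.

    All types share a lognormal baseline; each type up-weights its own marker
    block by ``marker_fold``.  Marker blocks sit at the end of the gene list
    so they never overlap the co-expression module blocks at the front.
    Derived from a dedicated sub-stream of the config seed, so the bulk
    generator and the single-cell reference generator see identical profiles.
    """
    rng = _streams(cfg, "celltypes")["celltypes"]
    base = np.exp(rng.normal(0.0, cfg.baseline_sd, cfg.n_genes))
    means = np.tile(base[:, None], (1, cfg.n_celltypes))
    for t in range(cfg.n_celltypes):
        hi = cfg.n_genes - t * cfg.marker_genes_per_type
        lo = max(0, hi - cfg.marker_genes_per_type)
        means[lo:hi, t] *= cfg.marker_fold
    return means / means.sum(axis=0, keepdims=True)


def simulate_expression(cfg: SimConfig) -> tuple[ExpressionMatrix, pd.DataFrame, SimTruth]:
    """Bulk counts, sample metadata and ground truth.

    Counts mix the cell-type mean profiles with each sample's true Dirichlet
    proportions, then apply the module-factor/covariate lognormal latent, so
    deconvolution against the matched single-cell reference can recover the
    proportions.  Returns the raw count matrix (genes × samples), the sample
    table and the SimTruth (which carries the true proportions).
    """
    cfg.validate()
    rng = _streams(cfg, "expression")["expression"]
    n = cfg.n_cases + cfg.n_controls
    genes = pd.Index([f"G{i:05d}" for i in range(cfg.n_genes)], name="gene")
    samples = pd.Index([f"S{i:03d}" for i in range(n)], name="sample")
    pheno = np.r_[np.ones(cfg.n_cases, int), np.zeros(cfg.n_controls, int)]
    sex = rng.integers(0, 2, n)
    batch = rng.integers(0, 4, n)
    pcr = rng.choice([14, 15, 16], n)
    props = rng.dirichlet(cfg.dirichlet_alpha, size=n)

    lab = module_labels(cfg)
    loading = cfg.within_module_cor

    # latent factors per module; associated modules shift in cases
    eta = np.zeros((cfg.n_genes, n))
    noise = rng.standard_normal((cfg.n_genes, n))
    for m in range(1, len(cfg.module_sizes) + 1):
        f = rng.standard_normal(n)
        if m <= cfg.n_assoc_modules:
            f = f + cfg.factor_effect * pheno
        idx = lab == m
        eta[idx] = loading * f + np.sqrt(1.0 - loading**2) * noise[idx]
    eta[lab == 0] = noise[lab == 0]

    # covariate effects: per-gene coefficients drawn around 0
    eff = cfg.covariate_effects
    covs = {
        "sex": (sex - sex.mean(), eff.get("sex", 0.0)),
        "pcr_cycles": (pcr - pcr.mean(), eff.get("pcr_cycles", 0.0)),
    }
    for name, (x, sd) in covs.items():
        if sd > 0:
            eta += np.outer(rng.normal(0.0, sd, cfg.n_genes), x)
    if eff.get("batch", 0.0) > 0:  # categorical: per-(gene, level) offsets
        offsets = rng.normal(0.0, eff["batch"], (cfg.n_genes, 4))
        eta += offsets[:, batch]

    mixture = _celltype_means(cfg) @ props.T  # genes × samples
    mean_expr = mixture * np.exp(cfg.bio_sd * eta)
    mean_expr /= mean_expr.sum(axis=0, keepdims=True)
    mu_lib, sd_lib = cfg.library_size_lognorm
    libsize = np.exp(rng.normal(mu_lib, sd_lib, n))
    counts = rng.poisson(mean_expr * libsize[None, :])

    expr = ExpressionMatrix(pd.DataFrame(counts, index=genes, columns=samples), layer="raw")
    table = pd.DataFrame(
        {"phenotype": pheno, "sex": sex, "batch": batch, "pcr_cycles": pcr}, index=samples
    )
    truth = SimTruth(
        module_label_per_gene=dict(zip(genes, (int(v) for v in lab))),
        assoc_module_ids=list(range(1, cfg.n_assoc_modules + 1)),
        true_proportions={
            s: dict(zip([f"CT{t}" for t in range(cfg.n_celltypes)], map(float, row)))
            for s, row in zip(samples, props)
        },
    )
    return expr, table, truth


def simulate_single_cell_reference(cfg: SimConfig) -> tuple[pd.DataFrame, pd.Series, SimTruth]:
    """Labelled single-cell counts with one distinct marker block per type.

    Returns (counts genes × cells, label per cell, truth carrying the
    per-type mean CPM profiles).
    """
    cfg.validate()
    rng = _streams(cfg, "reference")["reference"]
    genes = pd.Index([f"G{i:05d}" for i in range(cfg.n_genes)], name="gene")
    means = _celltype_means(cfg)

    cells, labels = [], []
    cell_lib = 5_000.0
    for t in range(cfg.n_celltypes):
        lam = means[:, t] * cell_lib
        cells.append(rng.poisson(lam[:, None] * np.exp(rng.normal(0, 0.1, cfg.cells_per_type))[None, :]))
        labels += [f"CT{t}"] * cfg.cells_per_type
    counts = pd.DataFrame(
        np.hstack(cells),
        index=genes,
        columns=[f"C{i:04d}" for i in range(cfg.n_celltypes * cfg.cells_per_type)],
    )
    truth = SimTruth(
        celltype_means={f"CT{t}": (means[:, t] * 1e6).tolist() for t in range(cfg.n_celltypes)}
    )
    return counts, pd.Series(labels, index=counts.columns, name="celltype"), truth


def _alleles(rng: np.random.Generator, m: int, palindromic_frac: float) -> np.ndarray:
    pairs = [ _NON_PALINDROMIC[i] for i in rng.integers(0, len(_NON_PALINDROMIC), m) ]
    n_pal = int(round(palindromic_frac * m))
    if n_pal:
        idx = rng.choice(m, n_pal, replace=False)
        for i in idx:
            pairs[i] = _PALINDROMIC[rng.integers(0, len(_PALINDROMIC))]
    return np.array(pairs)


def simulate_summary_stats(
    cfg: SimConfig, shared: bool
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SimTruth]:
    """GWAS and eQTL summary statistics over one region plus the LD matrix.

    ``shared=True`` places the same causal SNP in both traits; ``False``
    places two causal SNPs at least 10 positions apart.  A configurable
    fraction of eQTL rows has its alleles swapped (beta negated) to exercise
    harmonisation.
    """
    cfg.validate()
    if cfg.region_n_snps < 2:
        raise ValueError("region_n_snps must be >= 2")
    rng = _streams(cfg, "sumstats")["sumstats"]
    m = cfg.region_n_snps
    snps = [f"rs{i + 1:05d}" for i in range(m)]
    pos = 1_000_000 + 1_000 * np.arange(m)
    maf = rng.uniform(0.05, 0.5, m)
    se = 1.0 / np.sqrt(2 * cfg.sumstats_n * maf * (1 - maf))

    R = cfg.ld_decay ** np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
    L = np.linalg.cholesky(R + 1e-10 * np.eye(m))

    c_gwas = m // 2
    c_eqtl = c_gwas if shared else min(c_gwas + max(10, m // 10), m - 1)

    def marginal(causal_idx: int, beta: float) -> pd.DataFrame:
        z_causal = beta / se[causal_idx]
        z = R[:, causal_idx] * z_causal + L @ rng.standard_normal(m)
        return pd.DataFrame(
            {
                "snp": snps,
                "chr": "1",
                "pos": pos,
                "a1": "",
                "a2": "",
                "beta": z * se,
                "se": se,
                "maf": maf,
                "n": cfg.sumstats_n,
            }
        )

    gwas = marginal(c_gwas, cfg.gwas_beta)
    eqtl = marginal(c_eqtl, cfg.eqtl_beta)
    alle = _alleles(rng, m, cfg.palindromic_frac)
    gwas[["a1", "a2"]] = alle
    eqtl[["a1", "a2"]] = alle
    n_flip = int(round(cfg.allele_flip_frac * m))
    if n_flip:
        fl = rng.choice(m, n_flip, replace=False)
        eqtl.loc[fl, ["a1", "a2"]] = eqtl.loc[fl, ["a2", "a1"]].to_numpy()
        eqtl.loc[fl, "beta"] *= -1.0

    ld = pd.DataFrame(R, index=snps, columns=snps)
    truth = SimTruth(
        causal_snps={"gwas": snps[c_gwas], "eqtl": snps[c_eqtl]}, shared_causal=shared
    )
    return gwas, eqtl, ld, truth


def simulate_ppi(
    cfg: SimConfig,
    node_ids,
    hub_node: str | None = None,
    hub_targets=None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Erdős–Rényi PPI edge table with STRING-like per-channel scores.

    One designated node (``hub_node``, default the first of ``node_ids``)
    receives ``hub_extra_degree`` extra edges to ``hub_targets`` (default:
    all other nodes); those edges carry strong experiments/database scores so
    they survive channel exclusion.  Background edges activate each channel
    independently, so excluding channels prunes them realistically.
    """
    cfg.validate()
    node_ids = list(node_ids)
    if len(node_ids) != cfg.n_ppi_nodes:
        raise ValueError("n_ppi_nodes must equal len(node_ids)")
    rng = _streams(cfg, "ppi")["ppi"]
    n = len(node_ids)
    iu = np.triu_indices(n, k=1)
    present = rng.random(iu[0].shape) < cfg.ppi_edge_prob
    rows = []
    for i, j in zip(iu[0][present], iu[1][present]):
        scores = {c: 0.0 for c in PPI_CHANNELS}
        active = rng.random(len(PPI_CHANNELS)) < 0.4
        if not active.any():
            active[rng.integers(len(PPI_CHANNELS))] = True
        for c, a in zip(PPI_CHANNELS, active):
            if a:
                scores[c] = float(np.round(rng.uniform(0.15, 0.95), 3))
        rows.append({"protein1": node_ids[i], "protein2": node_ids[j], **scores})

    hub = hub_node if hub_node is not None else node_ids[0]
    targets = [t for t in (hub_targets if hub_targets is not None else node_ids) if t != hub]
    existing = {frozenset((r["protein1"], r["protein2"])) for r in rows}
    free = [t for t in targets if frozenset((hub, t)) not in existing]
    k = min(cfg.hub_extra_degree, len(free))
    for t in rng.choice(np.array(free, dtype=object), k, replace=False) if k else []:
        scores = {c: 0.0 for c in PPI_CHANNELS}
        scores["experiments"] = 0.9
        scores["database"] = 0.7
        rows.append({"protein1": hub, "protein2": str(t), **scores})

    edges = pd.DataFrame(rows, columns=["protein1", "protein2", *PPI_CHANNELS])
    if edges.empty:
        edges = pd.DataFrame(columns=["protein1", "protein2", *PPI_CHANNELS])
    from .master_regulator import combine_channel_scores

    edges["combined"] = combine_channel_scores(edges[list(PPI_CHANNELS)].to_numpy())
    truth = SimTruth(planted_hub_node=hub)
    return edges, truth


def simulate_gene_models(cfg: SimConfig, genes, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Non-overlapping gene bodies along one chromosome (0-based half-open)."""
    rng = rng or _streams(cfg, "genes")["genes"]
    starts = 10_000 + 60_000 * np.arange(len(genes))
    lengths = rng.integers(5_000, 40_000, len(genes))
    return pd.DataFrame(
        {
            "chr": "1",
            "start": starts,
            "end": starts + lengths,
            "gene": list(genes),
            "score": 0,
            "strand": np.where(rng.random(len(genes)) < 0.5, "+", "-"),
        }
    )


def write_fixture_bundle(outdir, cfg: SimConfig) -> dict:
    """Generate every pipeline input under ``outdir`` and return the paths.

    Writes counts TSV, sample TSV, single-cell reference TSVs, GWAS/eQTL
    summary-stat TSVs, LD TSV, BED gene models, BEDPE promoter interactions,
    PPI TSV, a small GMT collection and a truth JSON.  All files round-trip
    bit-identically through :mod:`comodmr.io`.
    """
    from . import io as cio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr, table, truth = simulate_expression(cfg)
    ref_counts, ref_labels, ref_truth = simulate_single_cell_reference(cfg)
    gwas, eqtl, ld, ss_truth = simulate_summary_stats(cfg, shared=True)
    lab = module_labels(cfg)
    assoc_genes = [g for g, l in zip(expr.gene_ids, lab) if 0 < l <= cfg.n_assoc_modules]
    nodes = assoc_genes[: cfg.n_ppi_nodes]
    if len(nodes) < cfg.n_ppi_nodes:  # pad with background genes
        nodes += [g for g in expr.gene_ids if g not in set(nodes)][: cfg.n_ppi_nodes - len(nodes)]
    if len(nodes) < cfg.n_ppi_nodes:  # fewer genes than requested PPI nodes
        cfg = replace(cfg, n_ppi_nodes=len(nodes))

    models = simulate_gene_models(cfg, expr.gene_ids[: max(50, sum(cfg.module_sizes))])
    # plant the hub at the associated-module gene nearest the shared causal
    # SNP, so the master regulator itself carries colocalisation evidence
    causal_pos = int(gwas.loc[gwas["snp"] == ss_truth.causal_snps["gwas"], "pos"].iloc[0])
    centres = models.set_index("gene")[["start", "end"]].mean(axis=1)
    candidates = centres.loc[centres.index.intersection(assoc_genes)]
    hub_gene = (candidates - causal_pos).abs().idxmin() if len(candidates) else assoc_genes[0]
    # the hub's extra interactions target the cis genes of the causal region
    # (the prospective colocalisation hits), mirroring a master regulator
    # wired to the genetically supported members of its modules
    cis = candidates.index[(candidates - causal_pos).abs() <= 900_000]
    targets = list(cis) if len(cis) >= 2 else assoc_genes
    ppi, ppi_truth = simulate_ppi(cfg, nodes, hub_node=hub_gene, hub_targets=targets)
    interactions = pd.DataFrame(
        {
            "chr1": "1",
            "start1": models["start"][:20] - 2_000,
            "end1": models["start"][:20],
            "chr2": "1",
            "start2": models["start"][:20] + 100_000,
            "end2": models["start"][:20] + 110_000,
            "gene": models["gene"][:20],
        }
    )
    gmt = {
        "MODULE1_LIKE": [g for g, l in zip(expr.gene_ids, lab) if l == 1][:50],
        "RANDOM_SET": list(expr.gene_ids[:: max(1, cfg.n_genes // 40)])[:40],
    }

    paths = {
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.tsv",
        "reference_counts": outdir / "reference_counts.tsv",
        "reference_labels": outdir / "reference_labels.tsv",
        "gwas": outdir / "gwas.tsv",
        "eqtl": outdir / "eqtl.tsv",
        "ld": outdir / "ld.tsv",
        "gene_models": outdir / "genes.bed",
        "interactions": outdir / "interactions.bedpe",
        "ppi": outdir / "ppi.tsv",
        "gene_sets": outdir / "sets.gmt",
        "truth": outdir / "truth.json",
    }
    cio.write_counts(expr, paths["counts"])
    cio.write_table(table, paths["samples"])
    cio.write_counts(ExpressionMatrix(ref_counts, "raw"), paths["reference_counts"])
    cio.write_table(ref_labels.to_frame(), paths["reference_labels"])
    cio.write_summary_stats(gwas, paths["gwas"])
    cio.write_summary_stats(eqtl, paths["eqtl"])
    cio.write_table(ld, paths["ld"])
    cio.write_bed(models, paths["gene_models"])
    cio.write_bedpe(interactions, paths["interactions"])
    cio.write_ppi(ppi, paths["ppi"])
    cio.write_gmt(gmt, paths["gene_sets"])
    merged = SimTruth(
        module_label_per_gene=truth.module_label_per_gene,
        assoc_module_ids=truth.assoc_module_ids,
        causal_snps=ss_truth.causal_snps,
        shared_causal=ss_truth.shared_causal,
        true_proportions=truth.true_proportions,
        planted_hub_node=ppi_truth.planted_hub_node,
        celltype_means=ref_truth.celltype_means,
    )
    paths["truth"].write_text(merged.to_json())
    return {k: str(v) for k, v in paths.items()}
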