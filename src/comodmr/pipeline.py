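"""End-to-end orchestration: simulate → QC → deconvolve → network →
associate → enrich → coloc + annotate → hub, with a deterministic manifest.

All randomness flows from the single config seed; rerunning with the same
config reproduces every output byte for byte, which the manifest records as
per-file SHA-256 checksums.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .annotation import annotate_snps, expand_proxies, filter_to_modules
from .association import AssociationConfig, associate_modules
from .coexpression import NetworkParams, build_network
from .coloc import ColocPriors, colocalise_genes
from .deconvolution import attach_proportions, build_signature, estimate_proportions
from .enrichment import ora_fisher
from .master_regulator import TopGeneConfig, build_top_gene_set, identify_master_regulator
from .matrix import validate_sample_table
from .preprocess import QCConfig, detect_outlier_samples, filter_genes, normalise_transform, residualise, select_variable_genes
from .simulate import SimConfig, write_fixture_bundle


@dataclass
class PipelineConfig:
    outdir: str = "comodmr_run"
    seed: int = 0
    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    network: NetworkParams = field(default_factory=NetworkParams)
    association: AssociationConfig = field(default_factory=AssociationConfig)
    coloc_priors: ColocPriors = field(default_factory=ColocPriors)
    top: TopGeneConfig = field(default_factory=TopGeneConfig)
    ld_r2_threshold: float = 0.7
    coloc_min_snps: int = 50
    inputs: dict = field(default_factory=dict)  # paths, used when simulate=False


def demo_config(seed: int = 0, outdir: str = "comodmr_run") -> PipelineConfig:
    """Reduced-scale configuration used for the bundled demonstration run.

    Same statistical structure as the study-scale defaults (unbalanced
    case/control groups, block modules with two associated, AR(1) LD with a
    shared causal SNP, a planted PPI hub) at a size that runs end to end in
    well under a minute.
    """
    sim = SimConfig(
        seed=seed,
        n_genes=1_200,
        module_sizes=(80, 60, 50, 40),
        n_assoc_modules=2,
        region_n_snps=150,
        n_ppi_nodes=140,
        hub_extra_degree=40,
    )
    cfg = PipelineConfig(outdir=outdir, seed=seed, sim=sim)
    cfg.qc.min_samples = min(cfg.qc.min_samples, sim.n_cases + sim.n_controls)
    cfg.top.seed = seed
    cfg.top.n_permutations = 2_000
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(cfg: PipelineConfig) -> dict:
    """Execute every stage; returns (and writes) the run manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cfg.simulate:
        cfg.sim.seed = cfg.seed if cfg.sim.seed == 0 else cfg.sim.seed
        inputs = write_fixture_bundle(outdir / "inputs", cfg.sim)
    else:
        inputs = dict(cfg.inputs)
        missing = [k for k, p in inputs.items() if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing pipeline inputs: {missing}")

    counts = cio.read_counts(inputs["counts"])
    samples = validate_sample_table(cio.read_table(inputs["samples"]), counts)

    # --- QC ---
    filtered = filter_genes(counts, cfg.qc)
    transformed = normalise_transform(filtered)
    outliers = detect_outlier_samples(transformed, cfg.qc)
    variable = select_variable_genes(transformed, cfg.qc)

    # --- deconvolution covariates ---
    ref_counts = cio.read_counts(inputs["reference_counts"]).values
    ref_labels = cio.read_table(inputs["reference_labels"]).iloc[:, 0]
    signature = build_signature(ref_counts, ref_labels, bulk_genes=counts.gene_ids)
    proportions = estimate_proportions(counts, signature)
    samples_cov, prop_cols = attach_proportions(samples, proportions)
    covariates = ["sex", "batch", "pcr_cycles", *prop_cols]

    # --- network on residualised expression ---
    residual = residualise(variable, samples_cov, covariates)
    modules = build_network(residual, samples_cov["phenotype"], cfg.network)

    # --- association ---
    assoc_cfg = AssociationConfig(
        fdr_level=cfg.association.fdr_level, covariates=prop_cols
    )
    assoc = associate_modules(modules.eigengenes, samples_cov, assoc_cfg)
    assoc_modules = [int(m.removeprefix("ME")) for m in assoc.index[assoc["significant"]]]
    assoc_genes = sorted(modules.labels.index[modules.labels.isin(assoc_modules)])

    # --- enrichment ---
    collection = cio.read_gmt(inputs["gene_sets"])
    universe = list(variable.gene_ids)
    enrich = {}
    for m in assoc_modules:
        enrich[m] = ora_fisher(modules.genes_in(m), collection, universe)

    # --- coloc on associated-module gene regions ---
    gene_models = cio.read_bed(inputs["gene_models"])
    gwas = cio.read_summary_stats(inputs["gwas"])
    eqtl = cio.read_summary_stats(inputs["eqtl"])
    assoc_models = gene_models[gene_models["gene"].isin(assoc_genes)]
    coloc_res = colocalise_genes(
        assoc_models, gwas, eqtl, cfg.coloc_priors, min_snps=cfg.coloc_min_snps
    )

    # --- GWAS lead annotation ---
    lead = gwas.loc[[(gwas["beta"].abs() / gwas["se"]).idxmax()]]
    ld = cio.read_table(inputs["ld"])
    proxies = expand_proxies(lead["snp"], ld, cfg.ld_r2_threshold)
    snp_table = gwas[gwas["snp"].isin(proxies)][["snp", "chr", "pos"]]
    interactions = cio.read_bedpe(inputs["interactions"])
    annotated = annotate_snps(snp_table, gene_models, interactions)
    annotated_modules = filter_to_modules(annotated, assoc_genes)

    # --- master regulator ---
    ppi = cio.read_ppi(inputs["ppi"])
    hub_summary: dict = {}
    if assoc_modules:
        top = build_top_gene_set(coloc_res, modules, assoc_modules, cfg.top)
        ppi_nodes = set(ppi["protein1"]) | set(ppi["protein2"])
        universe_ppi = sorted(set(assoc_genes) & ppi_nodes)
        top_in_universe = [g for g in top["gene"] if g in set(universe_ppi)]
        if top_in_universe:
            hub = identify_master_regulator(ppi, top[top["gene"].isin(top_in_universe)], universe_ppi, cfg.top)
            hub_summary = {
                "hub": hub.hub,
                "observed_max_degree": hub.observed_max_degree,
                "p": hub.p,
                "tied_hubs": list(hub.tied_hubs),
            }
    else:
        top = pd.DataFrame(columns=["gene", "coloc", "mm_gs"])

    # --- write outputs ---
    res_dir = outdir / "results"
    res_dir.mkdir(exist_ok=True)
    module_table = pd.DataFrame(
        {
            "module": modules.labels,
            "MM_own": [
                modules.membership.loc[g, f"ME{m}"] if m != 0 and f"ME{m}" in modules.membership else np.nan
                for g, m in modules.labels.items()
            ],
            "GS": modules.gene_significance,
        }
    )
    module_table.to_csv(res_dir / "modules.tsv", sep="\t")
    modules.eigengenes.to_csv(res_dir / "eigengenes.tsv", sep="\t")
    assoc.to_csv(res_dir / "association.tsv", sep="\t")
    for m, df in enrich.items():
        df.to_csv(res_dir / f"enrichment_module{m}.tsv", sep="\t", index=False)
    coloc_res.to_csv(res_dir / "coloc.tsv", sep="\t", index=False)
    annotated_modules.to_csv(res_dir / "annotation.tsv", sep="\t", index=False)
    top.to_csv(res_dir / "top_genes.tsv", sep="\t", index=False)
    (res_dir / "hub.json").write_text(json.dumps(hub_summary, indent=1, sort_keys=True))

    manifest = {
        "seed": cfg.seed,
        "config": {
            "sim": asdict(cfg.sim),
            "qc": asdict(cfg.qc),
            "network": asdict(cfg.network),
            "coloc_priors": asdict(cfg.coloc_priors),
            "top": asdict(cfg.top),
            "fdr_level": cfg.association.fdr_level,
        },
        "inputs": {k: _sha256(Path(p)) for k, p in sorted(inputs.items())},
        "outputs": {p.name: _sha256(p) for p in sorted(res_dir.glob("*"))},
        "stages": {
            "n_genes_filtered": filtered.n_genes,
            "n_genes_variable": variable.n_genes,
            "outlier_samples": outliers,
            "proportion_covariates": prop_cols,
            "n_modules": len(modules.module_ids),
            "assoc_modules": assoc_modules,
            "n_assoc_genes": len(assoc_genes),
            "n_top_genes": int(len(top)),
            "hub": hub_summary,
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
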