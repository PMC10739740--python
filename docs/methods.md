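# Methods

## Scope and model

`comodmr` infers case-associated co-expression modules from a bulk
gene × sample count matrix and asks whether a module member is a plausible
*master regulator*: a gene whose expression (a) summarises the associated
modules (high module membership), (b) tracks the phenotype (high gene
significance), (c) carries a genetically regulated component shared with a
disease GWAS signal (colocalisation PP4), and (d) is highly connected among
the top module genes in independent protein–protein interaction evidence.
The target setting is small unbalanced case/control cohorts (tens of
samples) where single-gene differential expression is underpowered and the
signal lives in correlated gene programmes.

## Preprocessing

Genes are kept when they reach ≥ `min_count` (5) counts in ≥ `min_samples`
(10) samples. Depth normalisation uses median-of-ratios size factors over
genes positive in every sample (library-size/geometric-mean fallback),
normalised to geometric mean 1 — size factors are only identified up to
scale — followed by `log2(x/sf + 1)`. A parametric variance-stabilising
transform is deliberately not reimplemented: all downstream statistics are
correlations, which are insensitive to the exact monotone transform; this is
a documented divergence from exact real-data reproduction. Sample outliers
are flagged (never silently dropped) when a sample's first merge height in
average-linkage Euclidean clustering of the top-100 expressed genes exceeds
mean + k·sd of all merge heights (k = 3 by default; the cut rule replaces a
visual tree inspection with an automatable criterion). Variable-gene
selection keeps the top fraction q = 0.75 by variance with count
`ceil(q·G)` and ties broken by gene id; at the reference scale of 12,810
genes this keeps 9,608 (a floor rule would keep 9,607 — the two conventions
differ by one gene). Covariates (sex, batch, PCR cycles, selected cell-type
proportions; categoricals one-hot with first level dropped) are removed by
per-gene OLS with the intercept added back; residuals are orthogonal to the
design at machine precision, and a rank-deficient design is an error naming
the collinear columns.

## Deconvolution

Cell-type proportions are estimated by non-negative least squares of bulk
CPM on a per-type mean-CPM signature built from a labelled single-cell
reference, renormalised to sum to one. A reference-based moment-matching
mode (bulk genes rescaled to the reference's per-gene mean/sd) is available
behind `rescale_bulk=True`. NNLS is used rather than a fitted-moment
transfer method because the proportions only serve as covariates and NNLS is
fully specifiable from first principles. Cell types with mean proportion
strictly > 5% are used as covariates; when *all* types pass, the
smallest-mean type is dropped as the reference category (the proportions sum
to one and would be collinear with the intercept).

## Network construction

Pearson correlation is the default estimator (the estimator is pluggable;
biweight midcorrelation was not required for planted-structure recovery).
The signed-hybrid adjacency zeroes negative correlations and raises positive
ones to the soft power β; β defaults to 6, and `pick_soft_threshold` scans
candidates 1–20 for the smallest β whose connectivity distribution fits
scale-free topology (log–log regression over 10 logarithmic bins, empty bins
dropped, R² counted only for negative slopes) at R² ≥ 0.8, falling back to
the argmax with a warning. Topological overlap uses the standard unsigned
formula with unit diagonal. Module detection is average-linkage clustering
of `1 − TOM` with a static cut at 0.995 of the maximum merge height, a
minimum module size of 30, and a second pass that reassigns unlabelled genes
to the module of their highest eigengene correlation when that kME > 0.3.
This replaces interactive dynamic tree cutting with an automatable,
testable rule; it recovers planted block structure (adjusted Rand
index ≥ 0.9 on 50 + 50-gene blocks at loading 0.8) but is not expected to
reproduce real-data module counts. Modules whose eigengenes correlate above
0.75 are merged iteratively (idempotent). Eigengenes are the unit-norm first
right singular vector of the standardised module block, oriented positively
against the module mean profile; MM is the gene–eigengene Pearson
correlation and GS the gene–phenotype correlation.

## Association and group tests

Each module eigengene is tested by logistic regression of case status on the
eigengene plus covariates; the Wald z on the eigengene coefficient gives a
two-sided p, corrected across modules by Benjamini–Hochberg (the procedure
behind "FDR" is taken as BH, the field default), significant at q < 0.20.
Perfect separation is detected (fitted probabilities reproducing the labels,
or exploding standard errors) and the module flagged non-estimable instead
of reporting divergent estimates; no Firth fallback is attempted. At the
default design (32 cases / 11 controls) the null rejection rate at p < 0.05
is measured at ≈ 0.03–0.05 over 1,000 null modules — slightly conservative,
as expected for a small-sample Wald test.

For subject-characteristics tables, 2×2 categorical variables use the
two-sided Fisher exact test when any expected cell count is below 5 and the
Pearson chi-squared test *without* continuity correction otherwise; numeric
variables use the two-sided Wilcoxon rank-sum test with normal approximation
and tie correction (no continuity correction). The expected-count rule is
adopted because it uniquely reproduces all four published categorical
p-values of the reference cohort table from their printed counts; a blanket
Fisher test does not.

## Enrichment

Over-representation of a module in each GMT set is the one-sided
hypergeometric tail P(X ≥ n) with the universe defaulting to the
post-filter network genes (a genome-wide universe can be supplied; it gives
systematically smaller p-values). `gene_ratio` is overlap divided by module
size in the universe (the wording of such ratios is ambiguous in parts of
the literature; this convention is fixed here). BH runs across sets within a
collection; output is ordered by (q, set name) for byte-stable files.

## Colocalisation

Per SNP and trait, the Wakefield log approximate Bayes factor is
`½log(1 − r) + z²r/2`, `r = W/(V + W)`, with prior effect sd 0.15 for
quantitative traits and 0.20 (log-odds) for case-control. Regional
hypothesis sums use log-sum-exp throughout; the H3 cross-term sum is
`S1·S2 − S12` computed with a signed log-space subtraction, so posteriors
remain finite for |z| ≤ 50 and sum to one within 1e−10. Priors default to
p1 = p2 = 1e−4, p12 = 1e−5 (all configurable — the upstream study states
none, so the conventional defaults are used, not asserted as the study's).
Harmonisation intersects on SNP id, flips the second trait's beta for
swapped alleles, and drops strand-ambiguous A/T and C/G SNPs; regions with
fewer than 50 surviving SNPs are skipped with a warning. Cis-regions are
gene body ± 1 Mb (field convention), clipped at position 0.

## SNP annotation

GWAS leads are expanded with proxies at r² ≥ 0.7 (square LD matrix or long
proxy table). Each SNP is annotated by three independent rules — gene-body
containment (0-based half-open), nearest gene ending before *and* nearest
gene starting after the position (distances from body boundaries, strand
ignored, both neighbours kept, since "closest preceding/following" is
ambiguous), and promoter-capture interaction other-end containment — and
the tagged union is intersected with associated-module genes.

## Master regulator

The top-gene set is the union of coloc-evidenced genes (PP4 ≥ 0.5) and
genes in the top decile of MM within their own module *and* of |GS| across
the combined associated-module genes (union semantics are the reading
consistent with the reference set being an order of magnitude larger than
its coloc subset; intersection is configurable, as are signed-GS and global
MM quantiles). Quantile cuts use lower interpolation so a cut of q → 0
includes every gene. PPI channel recombination removes the prior 0.041 from
each non-excluded channel, combines them as independent evidence and adds
the prior back once; with a single channel and no exclusions this is the
identity to 1e−12. Co-expression, neighbourhood and fusion channels are
excluded by default (they duplicate the information the modules were built
from); edges below combined score 0.4 are dropped. The hub is the
maximum-degree node of the subgraph induced on the top-gene set, ties broken
lexicographically and reported. Its significance is the add-one empirical p
of the observed maximum degree against B = 10,000 random same-size subsets
of the associated-module genes; p is therefore strictly positive and
monotone in the observed degree.

Because the maximum induced degree is integer-valued, the permutation p is
*discrete*: under the null it is super-uniform (P(p ≤ a) ≤ a, i.e. the test
is conservatively valid) but carries atoms the size of the statistic's modal
probability (~0.15–0.3 under Erdős–Rényi nulls), so its distribution departs
measurably from continuous U(0,1) — a property of any permutation test on an
integer statistic, not an implementation artefact. The test suite asserts
the valid property (super-uniformity) and keeps a strict
Kolmogorov–Smirnov uniformity check alongside it, which fails for exactly
this reason.

## Synthetic data

The generator emulates the study conditions: 32 cases vs 11 controls,
~10⁴ genes, block co-expression with 2–4 modules of which the first two
shift by 1.5 sd of the latent factor in cases (a moderate, detectable but
not trivial effect at n = 43), sex/batch/PCR covariate loadings, four CD4⁺
sub-populations with Dirichlet(10, 6, 2, 0.5) proportions — one type
averaging below the 5% covariate rule — 3'-seq-like library sizes
(lognormal, mean log 15.9 ≈ 8M reads), AR(1) LD with decay 0.9 per SNP
step, causal effects 0.5 at N = 10,000 (regional |z| ≈ 30), a 10% allele
flip fraction to exercise harmonisation, and an Erdős–Rényi PPI (p = 0.05)
with one planted hub whose extra edges target the cis genes of the causal
region. Counts are Poisson–lognormal: cell-type mean profiles (shared
deterministically with the single-cell reference generator, marker blocks
placed at the end of the gene list so they never overlap module blocks) are
mixed by the true proportions, multiplied by the exponentiated latent
(loading·factor + covariates + noise, biological sd 0.4) and scaled to the
library before Poisson sampling. Overdispersion enters through the
lognormal latent rather than a negative binomial because downstream stages
consume correlations, not count likelihoods. The expected within-module
latent correlation is the squared loading (0.64 at the default 0.8);
Poisson noise and depth normalisation attenuate the observed value
slightly, which is why recovery fixtures embed modules in a background of
unstructured genes — with too few background genes the median-of-ratios
reference itself absorbs the module factors.

What the generator does **not** emulate: read-level structure (FASTQ, UMIs),
scRNA-seq dropout, realistic LD panels, linkage between multiple causal
variants, degree-heterogeneous (scale-free) PPI topology, and real gene
annotation. Passing tests therefore demonstrate correctness of the
statistical machinery and recoverability of planted structure under the
assumed models, not agreement with any real cohort's numbers.

## Problem sizes and determinism

The bundled demonstration configuration (`demo_config`) runs the identical
stage chain at 1,200 genes / 4 modules / 150 SNPs / 140 PPI nodes, which
completes in about a second while preserving every statistical feature of
the study-scale defaults; the acceptance script aggregates recovery metrics
over three such runs. All randomness flows from a single seed through named
`SeedSequence` sub-streams per dataset, so every output — including run
manifests with per-file SHA-256 checksums — is byte-identical across reruns
with the same configuration.

## Known limitations

- Static tree cut + kME rescue approximates, but does not replicate,
  hybrid dynamic tree cutting; real-data module counts will differ.
- log2(x+1) differs from the parametric VST in low-count tails.
- Single-causal-variant colocalisation only (no SuSiE-style multi-signal
  decomposition, no conditional analysis).
- NNLS deconvolution ignores cross-subject expression variance that
  moment-transfer methods model; adequate for covariate use.
- The permutation null draws gene sets uniformly; it does not condition on
  degree or module composition of the observed set.
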