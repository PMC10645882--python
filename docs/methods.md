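# Methods

This note documents the statistical methods implemented in `hemonet`, the
design decisions behind them, and the deliberate simplifications. All
problem sizes quoted here (gene counts, sample sizes, module layouts) are
the package's own benchmark choices, not claims about any external cohort.

## Synthetic cohorts (`hemonet.synthetic`)

Counts are drawn from a **Gaussian copula over negative-binomial (NB2)
marginals**. For each sample, a latent standard-normal vector `z` is drawn;
genes belonging to a planted module with latent correlation `ρ` share a
module factor: `z_g = sqrt(ρ)·f + sqrt(1−ρ)·e_g`. The latent values are
mapped through the normal CDF to uniforms and then through the NB quantile
function at each gene's mean `μ_g` and dispersion `α` (NB2 variance
`μ + αμ²`). "Cancer" mode multiplies `μ_g` by `2^log2FC` for genes in the
differential-expression spec and restricts each planted module to a single
chromosome (plus, optionally, one dense pseudogene module drawn across
chromosomes); "control" mode spreads module members round-robin across
chromosomes, so planted edges are maximally trans.

Two seeds are separated on purpose: `param_seed` fixes the per-gene
baselines (log-uniform means in [20, 500], constant dispersion 0.15 by
default) while `seed` drives sampling. Cancer and control cohorts generated
with the same `param_seed` therefore share gene-level baselines, and
observed differences are attributable to the planted structure.

What the generator does **not** emulate: sequencing-depth variation per
sample, GC/length bias (the annotation carries GC and length, but counts
are not biased by them), batch effects, outlier samples, zero inflation
beyond what NB2 implies, and arbitrary (non-exchangeable) within-module
correlation structure. It is a benchmark for relative comparisons with
known ground truth, not a realism simulator.

Generator defaults (8 modules of 30 genes, ρ = 0.8) are the package's study
conditions. The acceptance cis-signal design instead uses 8 modules of 51
genes so the ~10,200 planted edges span the full 1e3–1e4 cutoff grid over
which the cis gap is measured; this is a measurement-design choice, fixed
before any results were inspected.

## Preprocessing (`hemonet.preprocess`)

Gene filtering removes a gene when **any** rule fires: mean expression at
or below the 25% quantile of gene means (type-7 quantile), zeros in more
than 50% of samples, or mean strictly below 10. Because the quantile
threshold depends on the surviving gene set, filtering is not naturally
idempotent; the report echoes the computed `quantile_value`, and passing it
back reproduces the same decision on a second pass.

GC-content and gene-length corrections are **within-sample full-quantile
normalizations across equal-frequency covariate bins**: within each sample,
genes are binned by GC (then by length), and each bin's values are replaced
by exact interpolation of the pooled reference quantile function at the
bin's mid-ranks, equalizing the distribution across bins while preserving
within-bin ranks. A `min_bin_size` guard (default 200 genes per bin)
reduces the number of bins on small gene sets and turns the step into the
identity when fewer than two bins are possible. This matters: with small
bins, within-bin rank competition couples unrelated same-bin genes and can
inject strong artificial dependence that mutual information then detects.

Between-lane normalization is full-quantile across samples (sorted columns
replaced by row means). TMM size factors follow the standard recipe —
M/A-value double trimming (30% / 5%), inverse-variance weights, reference
sample chosen by closest-to-mean upper quartile — and the returned factor
is the library size times the compositional TMM factor, normalized to unit
geometric mean. Batch-effect removal (e.g. ARSyN-style ANOVA
decompositions) is out of scope; a PCA separation table is provided as a
diagnostic instead.

## Co-expression (`hemonet.coexpression`)

Mutual information is the **plug-in estimator in bits** on equal-frequency
discretized profiles with `B = max(2, round(sqrt(n)))` bins. All pairs are
computed via per-bin one-hot indicator matrices and BLAS matrix products
(B² matmuls for the full joint histogram of every pair), which makes the
2,000-gene all-pairs matrix a few seconds of work. MI(X, X) equals log2(B)
exactly when B divides n. The plug-in estimator is positively biased at
small n; since edges are used through their ranking, the bias — which is
approximately constant across pairs at fixed marginal binning — does not
affect the analysis. Constant genes are assigned score 0.

Spearman correlation is computed by rank transformation and normalized dot
products. Edge significance uses a **pooled permutation null**: profiles
are permuted within gene, a fixed number of random pairs is scored per
permutation, and the add-one empirical p-value `(1 + #{null ≥ s}) / (1 + N)`
is attached to every edge. Edge lists are canonical: `gene_a < gene_b`,
sorted by descending absolute score with lexicographic tie-breaks, ranks
`1..E`.

## Topology (`hemonet.topology`)

The cis-fraction curve reports the share of intra-chromosomal edges among
the top-k edges over an ascending cutoff grid. Curves are compared with a
**two-sample KS test** on the curve values; D is the exact sup ECDF
difference and the p-value uses the asymptotic Kolmogorov distribution.
Caveat, carried on every profile object: the curve's points are serially
dependent (nested top-k sets), so the KS p-value is a summary of curve
separation, not a calibrated test of independent samples. The same KS
machinery applied to genuinely i.i.d. samples is calibrated (acceptance
checks the type-I error at n = m = 100).

Biotype pair fractions coarsen fine biotypes into families (any
`*pseudogene*` → pseudogene, `IG_*` → IG, `TR_*` → TR) and report the share
of each unordered family pair among the top-k edges. The component spectrum
annotates connected components with their modal chromosome and purity.

## Communities (`hemonet.communities`)

Louvain partitions are computed at 20 log-spaced resolutions in
[0.25, 4.0], with a per-resolution seed offset. HiDeF-style persistence
matches communities greedily across adjacent resolutions when Jaccard
≥ 0.75; a chain's **persistence** is its length, and chains shorter than 5
or whose consensus (members present in ≥ 50% of the chain) is smaller than
5 genes are dropped. Containment links between retained communities are
transitively reduced into a hierarchy. Resolution count, thresholds and
floors are package defaults chosen for desk-scale graphs.

## Differential expression and enrichment (`hemonet.de_enrichment`)

The DE stage is a deliberately simplified member of the DESeq family:
median-of-ratios size factors on the joint matrix, per-gene NB2 dispersion
by pooled method of moments (floored at 1e-8), log2 fold change of
normalized group means with a 0.5 pseudo-mean, a delta-method Wald z
against the normal, and Benjamini–Hochberg adjustment. Missing relative to
DESeq2: dispersion shrinkage toward a trend, Cook's outlier filtering,
independent filtering, and lfc shrinkage. Downstream analyses consume only
the sign and a significance flag, for which the simplified test is
calibrated (acceptance: null type-I in [0.03, 0.08]; planted log2FC = 2
recovered within ±0.2). Note that median-of-ratios absorbs any fold change
shared by all genes — an unavoidable identifiability limit — and a strongly
one-sided DE plant leaves a small compositional residual on null genes.

Over-representation is the one-sided hypergeometric upper tail of the
community/set overlap within the filtered gene universe, BH-adjusted across
all (community, set) pairs, with "enriched" meaning adjusted p < 1e-10.
The community **DE trend** is `(n_over − n_under) / n_total` in [−1, 1],
where over/under means BH-significant at α = 0.05 with the corresponding
sign and unclassified genes remain in the denominator. The cross-phenotype
shared-process matrix reports, for each gene set enriched in every
phenotype, the trend of the union of member genes of the communities
enriching it.

## Determinism

Every stochastic step draws from a `numpy` Generator seeded from the
pipeline seed plus a stage offset derived from a SHA-256 hash of the stage
name, so stages are independently reproducible and adding a stage does not
reseed the others. No timestamps or environment-dependent values enter any
artifact; two runs with the same seed are byte-identical.
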