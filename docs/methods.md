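# Methods

This note documents the statistical machinery implemented in `sigbench`,
the defaults it ships with, and the choices made where the design was
genuinely open.

## The benchmark idea

The toolkit scores differential-gene-expression (DGE) signature methods
by expected concordance between independent data types rather than
absolute ground truth. A drug perturbation signature should rank the
ChIP-seq target genes of the drug's TF targets highly; an inhibitory
drug's consensus signature should correlate with the CRISPR knockout
signature of its target gene. Both are "silver standards": noisy, but
unbiased with respect to the methods being compared, so relative method
rankings are meaningful even where absolute recovery is imperfect.

## Signature methods

All methods consume a gene × sample matrix and two disjoint sample
groups and emit one signed coefficient per gene (positive = higher in
treatment), plus a two-sided p-value for the test-based methods. Every
method is antisymmetric under swapping the groups.

**log2 fold change.** For counts, coefficient = mean log2(x + c) in
treatment minus the same in control, pseudocount c = 1. No library-size
normalisation is applied by default — the statistic is deliberately
self-contained — but a counts-per-million switch exists
(`MethodParams.cpm_normalize`). For signed log-scale profiles the group
means are differenced directly. Ranked by |coefficient| descending.

**Welch's t.** Per-gene unequal-variance two-sample t
(`MethodParams.equal_var` restores the pooled-variance test). Genes with
zero variance in both groups get coefficient 0 and p = 1, rather than
NaN, so the gene ranking is always total. Ranked by p ascending.

**Wilcoxon rank-sum.** The coefficient is the z statistic of the
treatment rank sum with midranks for ties and a tie-corrected variance.
The p-value is exact (full permutation null, via the Mann–Whitney exact
distribution) when both groups have ≤ 10 samples and no ties occur, and
the normal approximation otherwise. The exact small-sample branch keeps
the p-values honest at the group sizes where the normal approximation is
poorest; the z coefficient is used for direction in all cases.

**Characteristic direction.** The regularised linear-discriminant
direction between the two groups:

    b ∝ Σ_γ^{-1} (μ_t − μ_c),   Σ_γ = γ Σ̂ + (1 − γ) (tr Σ̂ / p) I,

where Σ̂ is the pooled within-group covariance and γ (default 0.5) the
shrinkage weight. The trace-scaled identity target keeps Σ_γ positive
definite at p ≫ n. The solve uses the Woodbury identity so only an
n × n system is formed (n = total samples), making the method cheap for
genome-sized matrices; a dense solve is used as the independent oracle
in the tests. b is normalised to unit Euclidean norm; its sign is fixed
by construction (bᵀ(μ_t − μ_c) > 0 since Σ_γ^{-1} is positive definite).
If both the pooled covariance and the mean difference vanish the
comparison is degenerate and an error is raised; if only the covariance
vanishes the mean-difference direction is returned.

**MODZ.** Replicate signatures are combined with weights
w_i ∝ max(ε, mean Spearman correlation of replicate i with the others),
ε = 0.01, normalised to sum 1. Correlations are computed over the full
common gene universe of the inputs (the original landmark-gene
convention is a special case when the inputs carry landmark genes only).
A single replicate passes through unchanged.

**External methods.** DESeq2/limma-style tools are exposed through a
registration contract rather than reimplemented: an adapter maps
(matrix, treatment, control) to a valid signature and may declare itself
counts-only, in which case signed log-scale input is refused — a count
model cannot consume signed values. The core test suite never requires
an external tool.

### Low-expression filter

Before RNA-seq analysis, a gene is kept iff its count is ≥ 10 in at
least k samples (k = smaller group size) and its total count is ≥ 15.
This restates the edgeR `filterByExpr` convention as an explicit,
self-contained rule; it is not a re-implementation of edgeR internals.

### Ranking and ties

Test-based methods rank genes by p ascending; coefficient-only methods
by |coefficient| descending. Ties break by |coefficient| descending then
gene id ascending, so every ranking is total and deterministic.

## Enrichment

Top-N up- and down-regulated gene sets (default N = 100; combined set =
union, up to 200) are extracted in ranking order; zero-coefficient genes
belong to neither direction. A hard cut-off accommodates methods without
significance scores and probes how concentrated each method's signal is.

Each library term is scored by the one-sided hypergeometric tail
p = P(X ≥ k) with X ~ Hypergeom(N, K, n): N the universe size, K the
term's genes in the universe, n the query size, k the overlap. The odds
ratio from the 2×2 table (Haldane 0.5 correction when a cell is zero)
breaks p ties, then term name. The universe defaults to the intersection
of the signature's genes with the union of library genes — the
information actually available locally — and can be fixed to an explicit
background list.

Term ranks are reported after an optional species filter (default: keep
human and mouse terms) and an explicit term blacklist, both applied
*before* re-ranking, so ranks always span 1..#surviving terms. The
random baseline draws size-matched uniform query sets (seeded) and pools
their ranks.

Gene symbols are upper-cased throughout so signature genes match
library genes regardless of source capitalisation.

## Bridge curves

For a ranked gene list and target set, y(k) = hits(k)/S − k/N — the
deviation of the target set's rank ECDF from the uniform CDF. It
increments on hits, returns to exactly zero at k = N, and peaks at
1 − S/N iff the top S genes are exactly the target set. The leading-edge
scalar is the mean of y over x ≤ x_max, reported at x_max = 0.01 and
0.02 side by side; the curve itself is the primary object and the scalar
is a summary choice, not a canonical definition. A GSEA-style ±increment
variant was considered and rejected as the default because the hit-ECDF
form matches the Brownian-bridge behaviour the evaluation assumes
(endpoint exactly zero, symmetric null).

Curves computed over universes of different size are aligned by step
interpolation onto a 1,000-point normalized-rank grid before averaging.
Averaging is two-stage where batch structure exists: curves are averaged
across a perturbagen's batches first, then across target terms — the
order matters when batch counts are unbalanced, and the batches-first
order is the one reported. Bridge curves are computed over the full
signature universe by default (configurable to library-covered genes
only).

## Batches and the L1000 convention

A batch is an opaque label for one cell line × timepoint group. Within a
batch, treatment samples are those whose perturbagen matches the query
and the control pool is *all other samples in the batch* — the
convention for normalized signed profiles where no explicit vehicle
control exists. Batches missing either group are dropped with a warning;
an explicit treatment/control metadata labelling is used instead for
RNA-seq-style designs. Gene identifiers are symbols throughout; probe
level identifiers are out of scope.

## Consensus signatures and drug–target recovery

Per-perturbagen consensus across batches: elementwise mean, median, or a
weighted average with weights ∝ max(ε, mean Pearson correlation with the
other inputs), ε = 0.01, normalised to sum 1. Flooring (rather than
allowing negative weights) follows the moderated-z convention and keeps
the output a convex combination; when all pairwise correlations are
equal the weighted average reduces exactly to the mean. Zero-variance
inputs get the floor weight with a warning.

The similarity matrix holds the Pearson correlation of every drug
consensus with every KO consensus; zero-variance vectors yield entry 0
with a warning (configurable policy). For target recovery the catalog is
filtered to inhibitor relations — an inhibitory drug should mimic its
target's knockout — drugs without a qualifying target among the KO
columns are dropped, and each drug's KO genes are ranked by correlation
descending (ties by gene id). The recovery curve reuses the bridge
machinery with the drug's known targets as the target set, averaged over
drugs. "Most opposite" drug prediction uses signed correlation
ascending, not |PCC|. Drugs with identical consensus vectors are kept
distinct.

## Synthetic data

The generators exist so every stage is testable offline, and their
defaults are the study conditions of the evaluation:

- **Counts**: 10,000 genes, 4 treated vs 4 control; NB(μ, α) counts with
  dispersion α = 0.1 and per-gene baselines μ ~ exp(N(5, 1)) — a
  log-normal spread that mimics bulk RNA-seq count ranges. One planted
  TF term of 50 genes whose treatment means are multiplied by 2^2.0,
  inside a library of 50 terms (49 size-matched decoys drawn from
  non-planted genes, so enrichment rank comparisons are fair).
- **Signed profiles**: 2 batches of 3 perturbation + 17 background
  samples; per-gene batch offsets N(0, 1); within-batch noise N(0, 1);
  planted genes shifted additively by the term effect.
- **Perturbation collections**: 50 drugs × 30 KOs over a 978-gene
  (landmark-sized) universe; 20 planted inhibitor pairs built as
  drug = ρ·KO + √(1−ρ²)·noise with ρ = 0.7, plus decoy activator
  relations.

What the generators do **not** emulate: library-size variation and
GC/length biases in counts, L1000 bead deconvolution artifacts,
correlated gene modules, or dose/time response. Passing benchmarks on
this synthetic data therefore demonstrates the machinery's correctness
and its ability to recover planted signal at realistic noise levels —
not method performance on real biology.

All generators are pure functions of their spec (seed included).

## Numerical choices

- p-values are clipped into (0, 1] (smallest positive float) so ranking
  keys never see 0 or NaN.
- The characteristic-direction Woodbury solve agrees with a dense solve
  to 1e-8 on small instances; unit norm holds to 1e-10.
- Fisher p-values use the scipy hypergeometric survival function and are
  exact to < 1e-12 against direct binomial-coefficient enumeration for
  all universes ≤ 25.
- Report tables are written with `%.10g` float formatting so identical
  runs are byte-identical.
- All randomness (simulation, random baselines) flows from explicit
  seeds; sub-seeds are derived with `numpy.random.SeedSequence`.

## Problem sizes used in the shipped analyses

The acceptance script and test suite run the planted-term benchmark at
50 simulation seeds (10,000 genes each), the bridge null at 1,000
permutations of a 1,000-gene universe, the two-gene discrimination trial
at 200 seeds, consensus recovery at 100 trials of 5 replicates × 200
genes, and drug–target recovery at 20 seeds of the 50 × 30 collection
with a 5-fold row-shuffled permutation null per seed. These sizes give
stable pass/fail margins for the properties being checked.

## Known limitations

- Enrichment is the Fisher test only; the running-sum evaluation is used
  for method comparison, not as a calibrated GSEA replacement.
- The log2FC default deliberately omits library-size normalisation;
  strongly depth-imbalanced designs should enable the CPM switch or use
  an external method adapter.
- The rank-sum exact branch is limited to tie-free groups of ≤ 10
  samples; beyond that the normal approximation is used.
- Consensus weighting assumes inputs on a common gene universe; no
  cross-universe alignment is attempted.
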