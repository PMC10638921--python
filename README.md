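# sigbench

Benchmarking toolkit for differential-expression signature methods, built
around a "silver standard" idea from pharmaco-transcriptomics: if a drug
engages a transcription factor (TF), then the genes that change under the
drug should overlap the TF's ChIP-seq target genes, and an inhibitory
drug's expression signature should resemble the CRISPR knockout signature
of its target. Neither relationship is a gold standard, but both give an
objective way to rank competing analysis methods: the better a method, the
higher it ranks the expected gene sets.

The package is for computational biologists comparing DGE pipelines on
bulk RNA-seq counts or on signed L1000-style expression profiles, and for
anyone mining perturbation signature collections for drug–target
relationships.

## What it computes

**Signatures.** For a treatment/control comparison, per-gene signatures by:

- `logfc` — difference of group means of log2(count + 1) (or of the signed
  values directly);
- `welch_t` — Welch's two-sample *t* per gene with two-sided *p*;
- `ranksum` — Wilcoxon rank-sum *z* per gene (exact *p* for small tie-free
  groups);
- `chdir` — the *characteristic direction*: the shrinkage-regularised
  linear-discriminant direction **b** ∝ Σ<sub>γ</sub><sup>−1</sup>(μ_t − μ_c)
  with Σ<sub>γ</sub> = γ Σ̂ + (1−γ)(tr Σ̂ / p) I, normalised to ‖**b**‖₂ = 1;
- `modz` — moderated-z replicate aggregation with weights from pairwise
  Spearman correlations.

External adapters (e.g. DESeq2 or limma-voom wrappers) can be registered
at run time; count-only adapters are refused on signed input.

**Evaluation.** Each signature's top-100 up, top-100 down, and combined
200 genes are scored against a GMT gene-set library by the one-sided
Fisher exact (hypergeometric) test, p = P(X ≥ k), X ~ Hypergeom(N, K, n),
computed locally. The rank of the expected TF's terms — against a
size-matched random-query baseline — is the figure of merit. A
running-sum *bridge curve* y(k) = hits(k)/S − k/N over the full ranked
gene list summarises how early the TF's target genes appear; its peak is
1 − S/N for a perfect ranking and its leading-edge mean (top 1–2% of
ranks) compares methods.

**Consensus and drug–target recovery.** Per-perturbagen consensus
signatures (mean, median, or correlation-weighted average across
batches), a drug × KO Pearson-correlation similarity matrix, recovery of
known inhibitor targets by per-drug correlation ranking, and top-k
similar/opposite drug prediction for a knockout gene.

**Synthetic data.** Negative-binomial count experiments with planted
differentially expressed gene-set terms, batch-structured signed
profiles, and drug/KO consensus collections with planted inhibitor pairs
— so every stage is testable without downloads.

## Worked example

```python
from sigbench import (BenchmarkConfig, SimulationSpec, filter_low_expression,
                      make_count_experiment, run_benchmark, summarize)
from sigbench.enrichment import selector_for_factor

spec = SimulationSpec(seed=42)         # 10,000 genes, 4 vs 4, 50-term library
matrix, metadata, library = make_count_experiment(spec)
matrix = filter_low_expression(matrix, (4, 4))
config = BenchmarkConfig(methods=["logfc", "welch_t", "ranksum", "chdir"], seed=7)
report = run_benchmark(matrix, metadata, library, selector_for_factor("TF001"), config)
print(summarize(report).head(5).to_string(index=False))
```

prints

```
 method direction  mean_rank  median_rank  q1_rank  q3_rank  n_obs  leading_edge  leading_edge_alt
  chdir  combined        1.0          1.0     1.00     1.00      1      0.339830          0.468557
  chdir        up        1.0          1.0     1.00     1.00      1      0.339830          0.468557
  logfc  combined        1.0          1.0     1.00     1.00      1      0.747507          0.866848
  logfc        up        1.0          1.0     1.00     1.00      1      0.747507          0.866848
ranksum  combined        1.0          1.0     1.00     1.00      1      0.063265          0.185140
```

Every method ranks the planted TF term first (mean_rank 1.0 of 50 terms)
for its up-regulated gene set — the planted effect is strong — while the
random baseline lands mid-library (mean rank ≈ 26–34). The
`leading_edge` column (mean bridge deviation over the top 1% of ranks)
separates the methods: here `logfc` concentrates planted genes earliest.
The `examples/` directory has one narrative script per capability,
including the L1000-style batch workflow and drug–target recovery.

## Command line

```sh
sigbench simulate counts --seed 11 --out data/
sigbench run --matrix data/matrix.tsv --metadata data/metadata.tsv \
    --gmt data/library.gmt --targets TF001 --methods chdir,logfc,welch_t \
    --n-top 100 --seed 7 --out report/
sigbench consensus --signatures sigs.tsv --method weighted --out cons.tsv
sigbench recover --drugs drugs.tsv --kos kos.tsv --catalog catalog.tsv --out rec/
sigbench predict --drugs drugs.tsv --kos kos.tsv --target KO0003 --k 100 --out pred/
```

Each run directory receives a `manifest.json` with the config snapshot,
seed, input digests and timings. A YAML config can mirror all flags
(flags take precedence).

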