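# debra

Differential representation analysis for clone-tracing DNA barcode counts.

## The problem

In cellular DNA barcoding experiments, clones are tagged with heritable
semi-random sequences and clone sizes are read out by sequencing barcode
abundances. Comparing a treated pool against controls identifies
*differentially represented barcodes* (DRBs) — clones with a distinct
phenotype. RNA-seq differential-expression tools (negative-binomial GLMs) are
commonly borrowed for this, but barcode counts violate their assumptions in a
specific way: a strong selection pressure (high drug dose, sorting,
xenografting) shrinks the treated sample to a small number of cells. This
*sampling bottleneck* (i) inflates the variance of the treated group far
above the controls', so a dispersion pooled across groups understates the
test-group noise, and (ii) makes low-abundance counts frankly non-NB (the
sampled cell numbers are small integers, so read counts cluster in multiples
of the per-cell read yield, with excess zeros). Both effects turn into false
positives — up to tens of percent of all barcodes on genuinely null
comparisons.

`debra` implements the DEBRA approach (DESeq-based Barcode Representation
Analysis) to both problems, together with a benchmark simulator and
evaluation machinery:

- **Test-group dispersions.** NB dispersions α in Var = μ + αμ² are
  estimated *only* from the test-group replicates (intercept-only model with
  size-factor offsets, Cox–Reid-adjusted likelihood), then either taken from
  a local mean–dispersion trend ("trended") or shrunk toward it by empirical
  Bayes ("shrunk").
- **β threshold.** A heuristic locates the mean-count level β above which
  counts are NB: sliding windows of mean-ordered barcodes are compared
  against their fitted NB(m, a) by two-sample Kolmogorov–Smirnov statistics;
  empirical and theoretical statistic populations are modelled as Gamma
  distributions, their density overlap is fitted with a four-parameter
  log-logistic curve of the mean count, and β is the mean count where the
  fitted overlap reaches 0.8 of the upper asymptote (if the curve ascends and
  the minimum overlap is below 0.25; otherwise β = 0).
- **β-bounded independent filtering.** Classical independent filtering picks
  the mean-count quantile threshold maximizing BH rejections at a target FDR;
  here the search is restricted to the quantile range [β, 1], so non-NB
  barcodes can never be re-admitted. Barcodes below β additionally receive
  the maximum tagwise dispersion as a belt-and-braces guard.
- **Tests.** Wald, likelihood-ratio, and a conditional per-condition exact
  test on normalized pseudo-counts; BH adjustment on the retained barcodes.
- **Benchmark simulator.** Two barcoded clone pools with log-normal clone
  sizes, mixed 50/50 and subsampled through configurable cell bottlenecks
  (null samples), optionally spiked with extra Pool-A cells (perturbed
  samples, known ground truth), then "sequenced" with per-cell PCR
  amplification noise.
- **Evaluation.** Ground-truth classification, empirical FDR, precision–
  recall curves with standardized partial AUC, a permutation ("random FDR")
  baseline, and local mean–variance / NB goodness-of-fit diagnostics
  (two-sample Cramér–von Mises with Monte Carlo p-values).

## Worked example

A null comparison: two 20k-cell bottleneck replicas tested against four
large controls (2 × 330k + 2 × 660k cells) drawn from the same 50/50 pool
mixture — no barcode is truly differential, so every call is a false
positive.

```python
import numpy as np
from debra import (simulate_pools, draw_sample, sequence_reads,
                   BarcodeCountMatrix, run_debra)

rng = np.random.default_rng(1)
pool_a, pool_b = simulate_pools(5000, rng)

cols, groups, names = [], [], []
for size, group, rep in [(330_000, "control", 1), (330_000, "control", 2),
                         (660_000, "control", 1), (660_000, "control", 2),
                         (20_000, "test", 1), (20_000, "test", 2)]:
    cells = draw_sample(pool_a, pool_b, size, degree=0.0, rng=rng)
    reads = sequence_reads(cells.cell_counts, depth=1_000_000, rng=rng,
                           pcr_overdispersion=1.0 / cells.total_cells)
    cols.append(reads); groups.append(group)
    names.append(f"{group}_{size // 1000}k.{rep}")

counts = BarcodeCountMatrix(
    np.concatenate([pool_a.barcode_ids, pool_b.barcode_ids]),
    np.column_stack(cols), names, groups)

results, beta = run_debra(counts, method="wald",
                          dispersion_method="trended", seed=1)
padj = np.nan_to_num(results["padj"].to_numpy(), nan=1.0)
print(f"beta threshold: {beta.beta:.1f} (valid={beta.valid})")
print(f"barcodes called at FDR 0.25: {(padj < 0.25).sum()} of {len(results)}")

pooled, _ = run_debra(counts, dispersion_columns="all",
                      beta_mode="off", apply_filter=False, seed=1)
padj_p = np.nan_to_num(pooled["padj"].to_numpy(), nan=1.0)
print(f"same data, pooled dispersions: {(padj_p < 0.25).sum()} false calls")
```

Output:

```
beta threshold: 826.0 (valid=True)
barcodes called at FDR 0.25: 1 of 10000
same data, pooled dispersions: 2818 false calls
```

The bottleneck-aware pipeline makes a single false call in 10,000 barcodes;
the same NB test with dispersions pooled over both groups — the unmodified
RNA-seq behaviour — calls 28% of all barcodes "differential" on data with no
signal whatsoever.

The same analysis from the shell:

```sh
debra simulate --seed 3 -o bench/           # counts, truth, manifest
debra test --counts counts.tsv --samples samples.csv \
    --method wald --dispersion trended --fdr 0.25 --beta auto --seed 3 \
    -o results.tsv
debra beta --counts counts.tsv --samples samples.csv --seed 3
debra evaluate --results results.tsv --truth bench/truth.tsv --fdr 0.25
debra gof --counts counts.tsv --samples samples.csv --seed 3 -o gof.tsv
```

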