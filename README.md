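# normsig

Normalization comparison and gene-signature validation for heterogeneous
two-class bulk expression cohorts.

## The problem

In small case/control expression studies (the motivating design: whole-blood
bead-array profiles from 56 cases and 28 controls), technical and biological
heterogeneity often carries more variance than the phenotype.  The choice of
normalization then silently decides the result: which genes pass FDR
control, how accurate a classifier appears, and whether a published
signature means anything.  `normsig` implements the full comparison as a
reusable pipeline for four regimes:

| regime | what it does | fitted? |
|---|---|---|
| `none` | natural log + per-sample median centering only | no |
| `quantile` | maps every sample onto the rank-wise mean reference | on training samples |
| `gfs` | gene fuzzy scoring — per-sample rank transform | no |
| `sva` | surrogate-variable correction (residual-SVD variant) | on training samples |

**Gene fuzzy scoring** maps each sample's genes to [0, 1] by descending
rank percentile: genes in the top θ1 score 1, genes below θ2 score 0, and
genes between score the interpolant (r − q(θ2)) / (q(θ1) − q(θ2)), with
θ1 = 5%, θ2 = 15% by default.  **SVA-lite** estimates latent heterogeneity
directions from the SVD of class-adjusted residuals (k chosen by
permutation parallel analysis) and removes them by regression with the
class effect protected.

Three read-outs compare the regimes, mirroring how such analyses are
reported:

1. **PC × factor association** — Kruskal–Wallis p-values of the top 10
   principal components against class and covariates; the rank of the first
   class-significant PC shows how prominently phenotype signal sits in the
   data.
2. **Cross-validation without selection** — median accuracy of a nearest
   shrunken centroid classifier over repeated stratified 50/50 splits using
   *all* genes: a direct measure of how much noise a regime leaves behind.
3. **Random-signature empirical p** — per split, select a signature on the
   training half (per-gene F-test + Benjamini–Hochberg, p ≤ 0.01), evaluate
   it, and evaluate a size-matched uniformly random gene set on the same
   split.  The empirical p is the fraction of splits where the random set
   is strictly better.  A signature whose empirical p is not small is not
   demonstrably better than noise — however accurate its classifier looks.

Because the motivating cohort is not public, the package ships a
first-class synthetic generator (56/28 design, 2,000 genes, planted 20-gene
signal, covariates, and a three-layer heterogeneity model) with ground
truth for recovery tests; see `docs/methods.md` for the model and its
limits.

## Worked example

```python
from normsig import (SyntheticSpec, generate_dataset, log_transform, median_center,
                     normalize, f_test_per_gene, select_signature,
                     cv_no_selection, cv_with_selection_and_null)

raw, factors, truth = generate_dataset(SyntheticSpec(seed=7))
logged = median_center(log_transform(raw))

for method in ("none", "quantile", "gfs", "sva"):
    report = cv_no_selection(logged, factors, method=method, n_splits=100, seed=1)
    print(f"{method:<9} median CV accuracy (all genes): {report.median_accuracy:.3f}")

sel = cv_with_selection_and_null(logged, factors, method="gfs",
                                 threshold=0.01, n_splits=100, seed=2)
print(f"gfs signature: median size {int(sel.signature_sizes.mean())}, "
      f"observed {sel.median_accuracy:.3f} vs random {sel.median_accuracy_random:.3f}, "
      f"empirical p = {sel.empirical_p:.3f}")

gfs, _ = normalize(logged, "gfs")
sig = select_signature(f_test_per_gene(gfs, factors.class_labels), 0.05)
hits = len(set(sig.gene_ids) & truth.signal_genes)
print(f"signature of {sig.size} genes at BH 0.05; {hits}/20 planted signal genes recovered")
```

prints

```
none      median CV accuracy (all genes): 0.667
quantile  median CV accuracy (all genes): 0.690
gfs       median CV accuracy (all genes): 0.952
sva       median CV accuracy (all genes): 0.810
gfs signature: median size 9, observed 0.929 vs random 0.667, empirical p = 0.000
signature of 17 genes at BH 0.05; 16/20 planted signal genes recovered
```

Reading it: with no normalization the classifier sits at the majority-class
rate (2/3) — heterogeneity drowns the signal; quantile helps a little by
fixing distribution-shape differences; SVA removes the leading latent
factor; GFS suppresses all three heterogeneity layers and recovers most of
the planted signal, and its selected signatures beat size-matched random
gene sets in every split (empirical p ≈ 0).

## Command line

Every stage is also a subcommand of the `normsig` CLI:

```
normsig simulate  --n-genes 2000 --seed 1 --out-prefix cohort
normsig normalize cohort_matrix.tsv --method gfs --out gfs.tsv
normsig pca-assoc gfs.tsv --factors cohort_factors.tsv --out-prefix gfs
normsig select    gfs.tsv --factors cohort_factors.tsv --threshold 0.01 --out-prefix gfs
normsig crossval  cohort_matrix.tsv --factors cohort_factors.tsv --method gfs \
                  --mode selected --splits 200 --seed 3 --out cv.json
normsig report    --out results/ --splits 200 --seed 5   # full comparison
```

Matrices are plain TSV (genes in rows, sample ids in the header); reports
are JSON.  `normsig report` writes per-regime association tables, gene
statistics, signatures, CV reports, an overlap report, a dendrogram of the
best signature (Newick), and a `summary.json` ranking the regimes on the
three read-outs — byte-identical across reruns with the same seed.

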