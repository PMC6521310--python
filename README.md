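# mirstrat

miRNA-stratified transcriptomic analysis: dichotomize a tumor cohort by the
expression of a single microRNA, find the genes that separate the resulting
high/low groups, discover molecular subtypes among them, and test whether the
miRNA's annotated target genes, signaling pathways and clinical phenotypes
carry the signal.

## The scientific problem

A microRNA that acts as a tumor suppressor leaves a footprint in the
transcriptome: samples in which the miRNA is scarce tend to de-repress its
target genes, and that shared de-repression can define a molecular subtype
with its own clinical behavior. Given a gene-expression matrix (genes x
samples), a per-sample miRNA abundance vector, and a curated list of the
miRNA's target genes, `mirstrat` runs the full chain of analyses that
quantifies this footprint:

1. **Preprocess** — keep genes detected in ≥ 80% of samples, drop samples
   whose signed biweight-midcorrelation connectivity is more than 5 SD from
   the cohort mean, and log2-transform with a floor at 1.
2. **Stratify** — label samples miRNA-*high* / *low* by strict comparison
   against the upper/lower q-quantile (default quartiles, linear
   interpolation between order statistics).
3. **Differential expression** — per-gene moderated t-test: the pooled
   variance is shrunk toward an empirical-Bayes prior estimated by moment
   matching on the log sample variances; Benjamini–Hochberg FDR control.
4. **Subtyping** — consensus non-negative matrix factorization
   (Kullback–Leibler multiplicative updates) on the top differentially
   expressed genes; the rank with the highest cophenetic correlation of its
   consensus matrix wins; entropy-based metagene feature extraction marks the
   genes that define each subtype.
5. **Target enrichment** — a one-sided Kolmogorov–Smirnov running-sum
   enrichment score of the target set among genes ranked by association
   (−log10 p) or fold-change magnitude, with a label-permutation null
   (default B = 10,000) and +1-smoothed empirical p.
6. **Pathway impact** — propagation of the DE fold-changes along signed
   directed pathway graphs (PF = (I − M)⁻¹ΔE), with a bootstrap p for the
   net accumulation tA combined with a hypergeometric over-representation p
   into a global pG = c − c·ln c.
7. **Clinical association** — likelihood-ratio tests of subtype labels
   against clinical binaries in a binomial GLM, optionally covariate-adjusted,
   plus paired qPCR relative-expression summaries.

A seeded synthetic-cohort generator plants recoverable signal at every one of
these stages, so the whole pipeline can be exercised and calibrated without
any external data.

## Worked example

Everything below is real output of the released code (seeds fixed as shown).

```python
from mirstrat.simulate import SimulationConfig, generate_cohort
from mirstrat.preprocess import normalize_log2, stratify
from mirstrat.diffexpr import moderated_t_test
from mirstrat.enrichment import run_target_enrichment

cohort = generate_cohort(SimulationConfig(seed=7))   # 2000 genes x 120 samples
expr = normalize_log2(cohort.expression)
strat = stratify(cohort.mirna, q=0.25)
# -> 30 high, 30 low samples; quantile cuts (3.807, 6.335) on the log2 scale

degs = moderated_t_test(expr, strat)
# -> estimated prior: d0 = 24.56, s0^2 = 1.0030
# -> 391 genes with p_adj < 0.05 (110 up, 281 down)

degs.sort_values("p").head(3)[["logFC", "t_mod", "p", "p_adj", "direction"]]
#            logFC      t_mod             p         p_adj direction
# G00989  6.152725  17.527681  1.471625e-29  2.943250e-26        up
# G00438  6.872869  17.009749  1.029831e-28  1.029831e-25        up
# G00292 -3.740966 -16.874576  1.720624e-28  1.147083e-25      down

assoc, mag = run_target_enrichment(degs, cohort.target_genes, B=10_000, seed=0)
# association: ES = 0.8511, NES = 33.13, p = 9.999e-05  (= 1/10001, the floor)
# magnitude:   ES = 0.8483, NES = 33.15, p = 9.999e-05
```

The planted target-set repression is so strong that the observed enrichment
score exceeds all 10,000 permuted scores, so the +1-smoothed empirical p sits
exactly at its floor 1/(B+1) = 1/10001 ≈ 9.99×10⁻⁵.

Subtyping on a three-cluster cohort (150 samples × 1000 genes, separation 3.0
log2 units, seed 7), consensus NMF over ranks 2–6 with 30 runs per rank on
the top-200 DEG submatrix:

```text
cophenetic correlation by rank:
  k=2: 0.9821   k=3: 0.9997   k=4: 0.9996   k=5: 0.9996   k=6: 0.9996
selected rank: 3
adjusted Rand index vs planted clusters: 1.0
```

### Command line

```bash
mirstrat simulate --out-dir demo --seed 7          # writes a full input set
mirstrat preprocess --expression demo/expression.tsv --out demo/norm.tsv
mirstrat stratify --mirna demo/mirna.tsv --q 0.25 --out demo/strat.tsv
mirstrat deg --expression demo/norm.tsv --stratification demo/strat.tsv \
             --out demo/degs.tsv
mirstrat enrich --deg-table demo/degs.tsv --targets demo/targets.txt \
                --out demo/enrichment.tsv -B 10000 --seed 0
# or everything at once from a YAML config:
mirstrat run-all --config config.yaml
```

`run-all` writes every stage's table plus `manifest.json` recording the
package version, seed, configuration and per-stage summary counts; rerunning
with the same configuration is bit-identical.

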