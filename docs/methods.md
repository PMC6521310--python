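# Methods

This note documents the statistical model behind each stage of `mirstrat`,
the default parameters and why they were chosen, what the synthetic generator
does and does not model, the numerical choices that affect results, and the
known limitations. No claim here goes beyond what the test suite actually
computes.

## 1. Preprocessing

**Expression filter.** A gene is kept when its value is strictly positive in
at least `min_nonzero_frac` of samples (default 0.8, boundary inclusive).
Rationale: genes detected in fewer samples contribute mostly zeros whose
log-floor value is constant and uninformative for a two-group t-statistic.

**Outlier removal.** Sample i's connectivity is
k_i = Σ_{j≠i} ((1 + bicor(x_i, x_j)) / 2)^β with β = 2 (signed soft
thresholding). `bicor` is the biweight midcorrelation: observations are
weighted by Tukey's biweight around the median with tuning constant c = 9 and
a mean-centred Pearson fallback when the median absolute deviation is zero.
Samples with standardized connectivity |Z| > 5 (one pass; `tail` selects
above/below/both) are dropped. A cohort whose connectivity is numerically
constant (sd below 1e-12 relative tolerance) has all Z = 0 by convention and
nothing is removed. Rationale: median/MAD weighting makes the correlation
robust to single aberrant samples, and |Z| > 5 only flags samples that are
extreme against the cohort's own spread.

**Normalization.** value → log2(max(value, 1)). The floor at 1 maps sub-unit
RPM-scale abundances to 0 and guarantees non-negative output, which the NMF
stage requires.

**Stratification.** Lower and upper q-quantiles (default q = 0.25) are
computed with linear interpolation between order statistics; a sample is
*high* iff strictly above the upper cut and *low* iff strictly below the lower
cut, everything else is excluded. Because of interpolation and strict
comparison, group sizes depend on ties and are never hard-coded; with 120
distinct values and q = 0.25 the groups are 30/30.

## 2. Moderated differential expression

For each gene, a two-sample t on log2 expression with the pooled variance
shrunk toward a prior: the prior (d0, s0²) is estimated by matching the first
two moments of log s² under a scaled chi-square model (digamma/trigamma
correction, trigamma inverted by Newton iteration), and the posterior variance
is s̃² = (d0·s0² + d·s²)/(d0 + d) with d0 + d degrees of freedom. d0 is capped
at 1e6 for the test statistic.

Two deliberate deviations from the common implementation of this scheme:

* When the observed spread of log s² is no larger than chi-square sampling
  noise, the prior df is infinite and s0² is set to the **mean** sample
  variance (not the bias-corrected exp-mean-log), so the infinite-shrinkage
  limit reproduces the ordinary pooled t exactly. The test suite pins this
  limit to `scipy.stats.ttest_ind` at 1e-8.
* A gene with zero within-group variance carries no sampling information of
  its own; it is reported with t = 0 and p = 1 (with a warning) rather than
  borrowing a prior-only variance.

Multiple testing uses an in-house Benjamini–Hochberg step-up (verified against
an exhaustive oracle for n ≤ 8 and against `statsmodels` on random input).
DEG selection is `p_adj < alpha` (default 0.05), ordered by raw p with gene id
as the deterministic tie-break, optionally truncated to `top_k`.

## 3. Consensus NMF subtyping

On the top-`top_k` (default 200) DEG submatrix (non-negative log2 scale):
Brunet-style multiplicative updates minimizing generalized Kullback–Leibler
divergence, seeded uniform(0,1] initialization, convergence when the KL
decrease over a 10-iteration window falls below tol × initial scale. The KL
trace is checked to be non-increasing in the tests.

For each rank k in `k_min..k_max` (default 2..6) the factorization is repeated
`n_runs` times (library default 200; the pipeline and acceptance settings use
30, which is sufficient because the consensus matrices stabilize far earlier
at these cohort sizes). Each run's connectivity matrix is the indicator that
two samples share the same argmax metagene; the consensus C̄ is their mean.
Stability is the cophenetic correlation between 1 − C̄ and the cophenetic
distances of its average-linkage dendrogram; the selected rank maximizes it,
ties resolved toward the smaller rank. Per-run seeds come from
`SeedSequence([seed, k, run])`, so results are independent of execution order.

Caveat: on *very* clean, well-separated data the merge of two planted clusters
can itself be perfectly reproducible, making several ranks tie at cophenetic
1.0 — the tie rule then prefers the smaller rank. Rank recovery is therefore
asserted at realistic noise levels (see the acceptance test), while the unit
tests check stability and partition correctness at the planted rank.

**Metagene features.** Gene score = 1 + Σ_k p_k log2 p_k / log2 K where p is
the gene's normalized loading row (0 for an all-zero row, 1 for a one-hot
row). A gene is selected when its score exceeds median + 3 × 1.4826 × MAD of
all scores *and* its maximal loading exceeds the median of that basis column —
i.e., cluster-specific and not merely low-expressed.

## 4. KS target enrichment

Genes are ranked by a per-gene statistic — association a = −log10 p (p floored
at 1e-300) or magnitude m = log10 max(2^|logFC|, 1 + 1e-12) — descending, ties
broken by gene id. A running sum climbs 1/|T| at targets and falls 1/|N|
elsewhere; the enrichment score is its maximum, equal to the one-sided
two-sample KS statistic D⁺ between target and non-target score distributions
(verified against a direct CDF-difference oracle). The null permutes the
target labels uniformly B times (default 10,000); the empirical p uses +1
smoothing, p = (#{ES_b ≥ ES_obs} + 1)/(B + 1), so its floor is exactly
1/(B + 1) — with B = 10,000, 1/10001 ≈ 9.99×10⁻⁵. NES is the z-score of the
observed ES against the permuted distribution; under the null it has mean ≈ 0
and SD ≈ 1 by construction (checked at B = 2000), but its distribution is not
exactly normal because ES is a running-sum maximum.

Over-representation analysis is the standard hypergeometric upper tail
P(X ≥ overlap), verified against exhaustive enumeration and Fisher's exact
test.

## 5. Pathway impact

For a signed directed pathway graph, M[g,u] = β_ug / N_ds(u) (edge sign over
the source's out-degree) and the perturbation factors solve
PF = (I − M)⁻¹ ΔE; Acc = PF − ΔE, tA = Σ Acc. Systems with reciprocal
condition number < 1e-10 (certain cycles) are reported as non-computable
rather than silently solved. Because tA is linear in ΔE (tA = c·ΔE with
c = column sums of (I − M)⁻¹ − I), the bootstrap permutes the full ΔE vector
and reduces each iteration to one dot product. pPERT is the two-sided,
median-centred +1-smoothed bootstrap p (default n_boot 20,000; the pipeline
and tests use 2,000, a prescribed scale-down, which bounds the p floor at
1/2001 — far above the 2e-6 global significance threshold, so that threshold
is effectively only reachable through pNDE at this setting). A degenerate null
(all permuted tA equal) returns pPERT = 1. pNDE is the hypergeometric
over-representation of DE genes on the pathway, and
pG = c − c·ln c with c = pNDE·pPERT (Fisher's product formula for two
independent uniforms). Activation status compares observed tA with the null
median.

## 6. Clinical statistics

Subtype/stratum labels enter a binomial GLM as dummy variables and are tested
with a likelihood-ratio chi-square against the covariate-only model (default
covariates: gender, age, location). Perfect separation is detected via
non-convergence or runaway coefficients (|coef| > 30) and reported as a
missing p rather than a spurious one. BH is applied across clinical features.

Wilcoxon tests use the exact distribution when both groups have ≤ 12
observations and no ties, otherwise the tie-corrected normal approximation;
paired data use the signed-rank test. qPCR relative expression defaults to the
ratio-of-Ct convention: rel = Ct(target)/Ct(reference) per tissue and
ratio = rel_tumor/rel_normal. Under this convention a ratio **above** 1 means
more cycles needed in tumor, i.e. *reduced* tumor expression; the summary
exposes both `frac_ratio_below_1` and `frac_reduced_expression` so the
direction is explicit. The 2^−ΔΔCt method is available as `method="ddct"`
(where reduced expression appears as ratio < 1). Tumor volume is the standard
caliper formula L·W²/2 with W ≤ L enforced.

## 7. Synthetic data generator — scope

`generate_cohort` draws log2 expression as gene baseline N(5, 2) + cluster
offset + N(0, noise_sd), exponentiated to an RPM-like scale. Only a fraction
`frac_informative` (default 0.15) of genes carry cluster offsets
(N(0, separation) per cluster), mimicking signature-gene structure; clusters
are balanced and randomly permuted. The miRNA value is 5 + effect for cluster
2, − effect for cluster 1, plus noise; target genes are repressed by
`target_shift` log2 units in samples whose miRNA lies above the cohort median.
Clinical binaries follow a logistic link on cluster-1 membership. Pathways
are random signed DAGs (edges run from lower to higher node index, so the
propagation system is always solvable) with optionally planted sign-coherent
fold-changes. The qPCR generator emits paired Ct values with a per-patient
baseline and a tumor-only shift on the target.

Not modeled: sequencing count noise (negative binomial), library-size
variation, batch effects, correlated gene modules beyond the planted cluster
offsets, censored survival outcomes, or realistic pathway topologies.

## 8. Numerical choices

* Quantiles: `numpy.quantile` linear interpolation; strict > / < at the cuts.
* Trigamma inverse: Newton iteration from 0.5 + 1/x with asymptotic branches
  below 1e-6 and above 1e7.
* Prior df cap 1e6 before forming the posterior variance (keeps df finite).
* Permutation/bootstrap nulls are vectorized with `Generator.permuted` on
  tiled matrices in chunks of ≤ 4e6 elements; results are identical to the
  loop implementation and deterministic per seed, independent of chunking.
* Derived seeds are always reduced mod 2³¹ − 1. Pipeline stage seeds come from
  `SeedSequence([seed, crc32(stage_name)])`, so adding or reordering stages
  does not shift the streams of existing stages.
* Linear systems use `numpy.linalg.solve` with an explicit reciprocal
  condition number check (1e-10) instead of relying on LAPACK's failure mode.

## 9. Limitations

* The moderated-t prior assumes a single shared variance prior across genes;
  mean–variance trends (as modeled by limma-voom for counts) are not captured.
* The enrichment null permutes target labels only: it tests whether targets
  have unusual scores, not the inter-gene correlation-aware null of a
  sample-permutation GSEA; p-values can be anti-conservative when target
  genes are strongly co-expressed.
* The KS statistic is the unweighted D⁺; no weighting by the ranking
  statistic.
* SPIA's pG assumes pNDE and pPERT are independent uniforms under the null;
  pNDE granularity on small universes makes pG conservative there.
* Consensus NMF assignments come from cutting the consensus dendrogram, not
  from the best single factorization; with ties at cophenetic 1.0 the smaller
  rank is preferred (see §3 caveat).
* The logistic separation guard (|coef| > 30) is a heuristic; very strong but
  genuine effects on small n can be flagged as non-converged.
* Clinical covariate adjustment treats age linearly and categoricals as fixed
  effects; no interaction terms.
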