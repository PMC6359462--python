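# Methods

## Scope and model

`netpert` analyzes a genes × samples expression study with a two-level
condition design ("normal" | "tumor") at three levels of perturbation —
single-gene expression, pairwise co-expression, and network modules —
and ranks perturbation signatures (paired up/down gene sets, e.g. from a
crowd-extracted drug/gene perturbation collection) by their potential to
reverse the disease signature. Two input matrices are accepted: raw
counts for the count-based differential-expression stage and a
depth-normalized expression matrix (fpkm-like) for the filtering and
correlation stages; the low-expression filter's surviving gene set is
applied to the count matrix by symbol intersection.

## Preprocessing

Genes are kept when they reach `min_level` (default 0.1, on the
depth-normalized scale) in at least `min_samples` (default 2) samples,
pooled across conditions. Quantile normalization is matrix-level: every
sample column is mapped onto the across-sample mean order-statistic
distribution, with ties receiving the average of the tied ranks'
reference values; the operation is idempotent to float tolerance.
Correlation stages consume `log2(quantile-normalized + 1)`. Negative
values are forbidden only for raw units (counts, fpkm); derived scales
may be negative.

## Differential expression

The classic exact-test family for two-group count data:

- **TMM factors.** The reference sample is the one whose upper-quartile
  expression fraction is closest to the cohort mean. Per sample,
  log-ratios M and abundances A against the reference are computed over
  genes positive in both, M trimmed 30% two-sided and A 5% two-sided,
  and the factor is 2^(inverse-variance-weighted mean of surviving M).
  Factors are rescaled to geometric mean 1.
- **Common dispersion.** Counts are scaled to a common effective library
  size (geometric mean of `library size × factor`); a single φ maximizes
  the sum over genes and groups of the conditional NB log-likelihood of
  the group's counts given their sum (size r = 1/φ). The optimizer is
  bounded on log φ ∈ [log 1e−6, log 10]; estimates at the lower bound
  are reported as exactly 0 (Poisson).
- **Exact test.** With equalized library sizes and shared φ, a group's
  sum is NB with size n_g/φ and the NB success probability cancels in
  the conditional distribution of the normal-group sum given the pair
  total. The two-sided p-value sums the conditional probability of all
  splits at most as likely as the observed one (ties included with a
  1e−10 relative guard); φ = 0 reduces to a binomial split test. log2
  fold changes (tumor over normal) use normalized group means with a
  0.125 prior count per group, so they are always finite.
- **Calls.** up = {q ≤ 0.05, logFC ≥ 1}, down = {q ≤ 0.05, logFC ≤ −1}
  with Benjamini–Hochberg q-values; both thresholds configurable. A
  user-supplied DEG table can replace this stage entirely.

The enumeration is exact, so runtime scales with the count totals; at
the simulated scales used here (~2000 genes, means ≲ a few hundred) the
stage runs in about a second.

## Differential co-expression

Per condition, Pearson correlation on the log scale with the Student-t
p-value (t = r√(n−2)/√(1−r²), n−2 df); |r| = 1 maps to p = 0. The
two-condition statistic is the standardized difference of Fisher
z-transforms, dz, with variance 1/(n₁−3) + 1/(n₂−3). For the dz
computation correlations at |r| = 1 are clamped to 1 − 1e−12; the
`fisher_z` primitive itself raises on |r| ≥ 1 rather than clamping
silently. Genes constant within a condition are excluded with a warning,
never reported as r = 0.

Two p-values are reported per pair:

- **Asymptotic**: 2Φ(−|dz|).
- **Empirical**: condition labels are permuted `n_perm` times, dz is
  recomputed for all pairs each round, and all permuted values are
  pooled into one null sample; p = (1 + #{|null| ≥ |dz|}) / (1 + N).
  Pooling across pairs is the only way a finite number of permutations
  can grade extreme pairs at all, and even so the resolution floor is
  1/(1+N). Pairs at the floor therefore fall back to the asymptotic
  p-value and are flagged `tail_extrapolated`; this is how the default
  significance threshold of 1e−20 — far below any permutation floor —
  is adjudicated.

Pairs are classified per condition as "+", "−" (p ≤ class_alpha = 0.05,
sign of r) or "0", giving nine classes, and into (r_normal, r_tumor)
sign quadrants; quadrant II (− → +) and IV (+ → −) pairs flip
correlation sign, and their gene union feeds the refined disease
signature. Enumerating "all" pairs is guarded at 5000 genes; above that
the top 2000 genes by variance are used (both configurable).

## Network modules

Unsigned adjacency |cor|^β (signed variant available). β is chosen by
the scale-free topology criterion: connectivity k_i = Σ_{j≠i} a_ij, the
degree distribution is binned into 10 equal-occupancy bins, and log10
density is regressed on log10 mean connectivity; R² counts only when the
slope is negative. The smallest β with R² ≥ 0.8 is chosen, else the
argmax. Equal-occupancy bins (rather than equal-width) keep every bin
populated under the extremely skewed degree distributions that
soft-thresholding produces; with planted-block-plus-noise data this
criterion lands at moderate powers (β ≈ 4–12).

Topological overlap TOM_ij = (L_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij),
L_ij = Σ_{u≠i,j} a_iu a_uj. Modules come from average-linkage
hierarchical clustering of 1 − TOM with a *static* height cut (default
0.995) — simpler and fully deterministic compared with dynamic
hybrid cutting, and sufficient for planted-block validation; clusters
below `min_module_size` (30) become "grey". Labels are size-ranked
color names (turquoise, blue, brown, …); genes are sorted internally so
the assignment is invariant to input order, with size ties broken by the
lexicographically smallest member. Cross-condition comparison reports
overlap counts and one-sided hypergeometric p-values on the shared gene
universe. An optional sample-outlier step removes samples whose first
merge height in a sample dendrogram exceeds the median by more than 2.5
MADs; it is off by default in simulations.

## Reversal ranking

The universe is the intersection of assayed genes with genes appearing
anywhere in the signature database — both margins of the 2×2 table must
be observable. For a disease signature (up, down) and a perturbation
signature (up', down'):

- p_rev_up = one-sided hypergeometric tail of |up ∩ down'| against
  (|up|, |down' ∩ universe|, |universe|); p_rev_down symmetric.
- p_combined = Fisher's method on the two one-sided p-values (χ², 4 df),
  degenerating to the single available p when a disease side is empty.
  Underflowed p-values are floored at the smallest normal double before
  the log. Fisher's method operationalizes "overlap on either side
  promotes a drug" as evidence pooling; min-p with a Bonferroni factor
  is a reasonable alternative but changes only tie handling in practice.

Signatures are ranked by ascending raw p_combined (ties: p_rev_up, then
id, so the output is independent of database order); BH-adjusted values
are reported alongside but do not affect the order. Databases often
contain several signatures per drug name, so a collapsed best-per-name
view is emitted as a secondary output. The refined ranking replaces the
DEG signature with DEGs ∩ sign-flip rewired genes. A generic
over-representation routine (gene set vs named GMT collections) is
included; no term database is bundled.

## Synthetic data

One latent Gaussian layer per condition encodes the correlation
structure: shared co-expression modules (equicorrelated blocks),
rewired blocks realized as disjoint gene *pairs* with per-condition
correlations (avoiding the positive-definiteness ceiling that large
negative equicorrelation blocks would hit; a nearest-PSD eigenvalue
projection guards arbitrary user-supplied blocks). Counts are produced
by pushing latent normal quantiles through the NB quantile function with
gene base means drawn log-normal, per-sample depth factors uniform in
1 ± 0.3, and tumor means shifted by the planted log2 fold change. The
monotone quantile map approximately preserves latent correlations on the
log-count scale — extreme correlations (|r| ≳ 0.99) attenuate by ~0.01
through discretization, and quantile normalization over very few genes
(tens) distorts further, so correlation-level checks use either the
Gaussian layer or matrices with a realistic gene count.

Planted up-DEGs deliberately cover the first rewired block's genes and
down-DEGs the second block's, so the expression-level and
rewiring-level perturbations overlap as they do in real tumors and the
refined disease signature is non-empty. The signature generator plants
reversers that take a fidelity fraction of disease-up genes into their
down-set (and vice versa), padded back to size with random genes, among
size-matched random decoys.

Default scenario: 2000 genes, 60 normal / 200 tumor samples, three
50-gene modules at intra-correlation 0.7, two rewired blocks of 10 pairs
((−0.5 → 0.9) and (0.7 → −0.7)), 200 up / 100 down DEGs at |log2FC| = 2,
NB dispersion 0.1, 200 signatures. These effect sizes make every planted
structure recoverable by its stage, and a full pipeline run completes in
about a minute on one CPU. All generators are pure functions of
(config, seed).

What the generator does *not* emulate: GC/length biases, batch effects,
outlier samples, heavy-tailed dispersion heterogeneity, and correlated
decoy signatures. Passing recovery tests therefore demonstrate
correctness of the statistical machinery at the stated effect sizes, not
performance on any particular real cohort.

## Numerical choices and edge cases

- Correlations are clipped into [−1, 1] after `corrcoef` to absorb float
  drift; constant vectors raise a dedicated error.
- BH adjustment is the standard step-up with a running minimum from the
  largest p; q ≥ p elementwise and monotone in sorted order.
- The empirical-p floor convention guarantees p > 0; dz = 0 yields p = 1.
- TOM denominators of 0 (isolated gene pairs) yield TOM = 0.
- The exact test rounds equalized pseudo-count sums to integers before
  enumeration.
- Module-size ties and gene order are broken by sorted gene symbol
  everywhere, making outputs byte-reproducible for a fixed seed.

## Worked-example discrepancy

The published differential-co-expression table that the worked examples
reproduce is internally inconsistent about the normal-cohort size: its
first row's printed p-value matches the Student-t test at n = 56 (the
stated cohort size), while two other rows match only at n = 58. The
package reproduces each printed value at the sample count it implies and
makes no attempt to force a single n. The printed differential p-value
of the top pair (~1e−102) is also not recovered by the asymptotic
z-difference at the stated sizes (which gives ~1e−106); both the
asymptotic and the empirical p are therefore always reported side by
side.

## Known limitations

- Common (not tagwise/trended) dispersion; no GLM designs or covariates.
- Static tree cut; no module eigengenes or module–trait statistics;
  networks above ~20k genes are out of scope.
- The exact test's full enumeration is impractical for very deep
  libraries (totals ≫ 10⁶).
- Signature scoring is overlap-based (Fisher exact), not rank-based
  (GSEA/KS-style connectivity scoring).
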