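# Methods

## Model and procedure

`netmod` treats a case/control expression study as a pair (Z, Y): a
gene × sample matrix of per-gene Z-scores and a binary phenotype. A
*gene module* is a connected node set of the PPI network; its expression
X is the unweighted per-sample mean of member Z-scores (the same
"normalized average" later used as the classifier feature, so the score
being optimized and the feature being evaluated are one quantity).

The **activity score** is the empirical mutual information, in bits,
between the discretized X and Y. X is binned into `n_bins` equal-width
intervals spanning `[min(X), max(X)]`, half-open `[s_k, s_{k+1})` with
the last bin closed; probabilities are empirical frequencies and
`0·log(0) = 0`. MI is clipped at 0 to absorb `-0.0` from floating-point
cancellation. Binning is recomputed from the candidate module's own X
range at every greedy evaluation, since the range of a module average
changes as members join; a global binning would make early and late
candidates incommensurable.

**Greedy growth** starts from each seed gene. Each step scores every
network neighbor of the current member set by the AS of the enlarged
module and admits the argmax only on *strict* improvement (ties in the
candidate argmax break to the lexicographically smallest symbol). Strict
improvement prevents size drift along score plateaus — important
because empirical MI saturates at H(Y) ≤ 1 bit once the binned module
average separates the classes perfectly. Growth stops on no
improvement, exhausted neighbors, or `max_size`. One module is grown
per seed; exact-duplicate member sets are collapsed keeping the
highest-scoring record.

**Significance.** Three permutation nulls are attached to each module,
all with the add-one tail estimator p = (1 + #{AS_null ≥ AS_obs}) /
(1 + n_perm), so p ∈ (0, 1] and is never exactly zero:

- *phenotype permutation*: shuffle Y (class counts preserved exactly),
  rescore the fixed member set;
- *random gene sets*: same-size draws from the expression gene universe,
  scored with the true Y;
- *random gene sets retaining the seed*: as above with the seed forced
  into every draw.

The nulls rescore the module **as built**; they do not rerun the greedy
search under permuted labels. The phenotype-permutation p therefore
carries the usual post-selection optimism, which is why selection also
demands an absolute activity score (AS ≥ 0.34) and all three tests
simultaneously (P < 0.001 each). Random-gene-set draws deliberately
ignore connectivity: the hypothesis being tested is "better than an
arbitrary same-size gene set", not "better than a rewired subnetwork".

**Module eQTL.** For each sufficiently mutated gene (≥ 3 mutated
samples) and each expression gene, expression is regressed on binary
mutation status; for a binary predictor the slope t-test is identical to
the pooled-variance two-sample t-test, which the test suite checks
numerically. The scan runs on tumor samples only — somatic status is a
tumor property, and carrying normals (all status 0) would let any
tumor-vs-normal differential gene masquerade as an eQTL target. BH FDR
is computed once over all tested pairs. A mutated gene links to a module
when any member passes FDR < 10⁻⁴ (the any-member rule); driver tables
count distinct mutated genes per module and modules per mutated gene.
Pairwise mutual exclusivity of two mutated genes uses the two-sided
Fisher exact test with a Haldane-corrected odds ratio.

## Parameters that matter

| parameter | default | units / range | rationale |
|---|---|---|---|
| `min_expression` | 0.1 | FPKM-like | genes below this mean in *both* classes are dropped |
| `edge_percentile` | 0.05 | fraction | edges in the bottom fraction of **both** \|corr\| and \|Δcorr\| rankings are removed; intersection bound ⇒ at most 5% of edges can go |
| `n_bins` | Sturges ⌊log₂ n + 1⌋, cap 10 | bins | unstated in the method's description; Sturges tracks sample size, the cap keeps cells populated |
| `max_size` | 20 | genes | runtime guard far above the expected median module size (~6) |
| `n_perm` | 1000 | draws | resolves p ≈ 10⁻³ with the add-one estimator (floor 1/1001) |
| `as_min`, `p_max` | 0.34, 0.001 | bits, prob | DGM selection rule (AS inclusive ≥) |
| `eqtl_fdr` | 10⁻⁴ | BH FDR | any-member linking cutoff |
| `fc_min`, `deg_fdr` | 2, 0.01 | linear FC, FDR | DEG baseline; both criteria required simultaneously |
| `folds` | 3 | — | stratified CV for the sigmoid-kernel SVM |

Z-scores use the sample (n−1) standard deviation; constant genes map to
all-zero rows (with a warning) rather than erroring so that
flat-expression interactors remain usable as members. Fold changes use a
pseudocount of 1 on linear-scale class means; matrices containing
negative values are treated as already log-scale and tested raw, with
class means shifted non-negative for the ratio. Edge correlations for
constant genes are set to 0, not NaN. Ranking ties in the edge filter
break lexicographically so results are order-independent.

## What the simulator emulates — and what it does not

`netmod.simulate` produces a connected preferential-attachment network,
Z-scale background expression N(0, 1), planted connected modules whose
members shift by +δ in tumors (gated by a Bernoulli driver mutation when
one is assigned), passenger mutations with no expression effect, and a
GMT with one term per planted module plus random terms. An exponential
transform emits FPKM-like positive values, optionally with off-network
near-zero genes to exercise the expression filter. Everything is
deterministic under a seed and the planted truth round-trips to JSON.

It does **not** emulate count-based RNA-seq noise, batch effects,
correlated background co-expression, copy-number or methylation
confounding, or hub-biased interaction false positives. Passing tests
therefore demonstrate correctness and calibration of the algorithms
under clean planted signal, not performance on real cohorts.

Benchmark conventions chosen here (the generator's conditions, fixed
once): planted-module recovery uses one planted module per replicate —
when several modules are planted with the same tumor-wide shift their
association with Y is identical and no phenotype-MI score can attribute
members between them, so the multi-module version tests an
unidentifiable problem; "recovered" is the best-Jaccard match among the
deduplicated built module set, i.e. the pipeline's actual output. The
greedy-vs-exhaustive comparison uses the package's own network generator
at mean degree 2: at 8–12 nodes a realistic PPI subnetwork is sparse,
and dense random graphs mostly measure the MI estimator's small-sample
noise-chasing over 6-node subsets rather than search quality. The
driver-eQTL benchmark feeds the generator's Z-scale output directly to
the scan so that "members shifted by 1 SD" is exactly what the scan
sees; re-standardizing first would shrink the stated shift (it
contributes to the per-gene variance).

## Numerical and design notes

- The correlation edge filter uses absolute values in both rankings: a
  strong negative correlation is still evidence of a functional link.
  The literal bottom-fraction-of-both rule removes at most
  ⌊percentile·m⌋ edges; `percentile` is exposed because the rule's
  aggressiveness is data-dependent.
- Per-module RNG streams are derived from (master seed, CRC32 of the
  seed gene), so significance results are independent of module
  evaluation order and safe under parallel scheduling.
- SVM features are standardized per column inside each training fold
  (sigmoid kernels are scale-sensitive); folds are stratified to
  protect heavily imbalanced cohorts; the reported AUC pools
  out-of-fold decision values (per-fold AUCs are also available).
- Hierarchical clustering is average-linkage on Euclidean distances cut
  at two clusters; "misclustered" is the complement of the best of the
  two cluster↔class assignments.
- Enrichment is the upper-tail hypergeometric P(X ≥ k) with term genes
  intersected with the universe (all genes surviving the expression
  filter); k = 0 reports p = 1.
- Degenerate inputs fail fast with typed errors (`ConfigError` exit 2,
  `DataError`/`ParseError` exit 3 in the CLI); missing expression values
  are rejected rather than imputed.

## Problem sizes

Default test and acceptance workloads are desk-scale by design: 60–100
gene networks, 50–150 samples, 200–1000 permutations, 20-replicate
recovery benchmarks. These sizes keep every property check (MI oracle
equivalence at 10⁻¹², exhaustive-search bounds on ≤ 12-node graphs,
KS-uniformity of 500 null module p-values, full-pipeline byte-identical
reruns) fast enough to run routinely; the pipeline itself is vectorized
(batched MI scoring, matrix regression scans) and scales to larger
inputs linearly in edges × samples for the filter and seeds ×
neighbors × samples for the search.

## Known limitations

- The greedy search is a local optimizer; the exhaustive-search bound is
  only verified on small graphs.
- Empirical MI saturates at H(Y): with strong signal, growth can stop
  before a planted module is complete (members beyond empirical perfect
  separation add nothing strictly positive). Recovered modules are
  accordingly biased toward compact cores.
- Permutation p-values are optimistic for modules selected by the same
  score (see above); the random-gene-set nulls mitigate but do not
  remove this.
- The eQTL stage models mutation effects as mean shifts with a single
  binary predictor and no covariates; confounding by copy number,
  methylation or purity is out of scope.
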