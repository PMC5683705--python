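# netmod

Differential gene-module discovery on protein-interaction networks and
module-based eQTL mapping of somatic mutations.

## The problem

In tumor/normal expression studies, single differentially expressed
genes (DEGs) are noisy biomarkers, and driver mutations often act on
whole pathways rather than on the mutated gene's own expression.
`netmod` implements a two-stage systems approach for case/control
cohorts (e.g. clear cell renal cell carcinoma tumors vs. matched normal
tissue):

1. **Differential gene modules (DGMs).** Starting from every gene as a
   seed, a module grows greedily along protein–protein interaction (PPI)
   edges. A candidate neighbor joins the module if it increases the
   *activity score*

   AS(X; Y) = Σ_k Σ_y p(x∈bin_k, y) · log₂ [ p(x∈bin_k, y) / (p(x∈bin_k) p(y)) ],

   the empirical mutual information (bits) between the equal-width
   discretized module-average Z-score expression X and the binary tissue
   phenotype Y. Each module is vetted against three permutation nulls
   (phenotype shuffling, random same-size gene sets, random gene sets
   retaining the seed); modules with AS ≥ 0.34 and all three
   permutation P < 0.001 are selected as DGMs.

2. **Module-based eQTL.** Each (mutated gene, expression gene) pair is
   tested by linear regression of expression on binary somatic-mutation
   status across tumor samples, with Benjamini–Hochberg FDR over the
   whole scan. A mutated gene is linked to a DGM when *any* member gene
   passes FDR < 10⁻⁴ — prioritizing candidate drivers whose mutations
   move whole expression programs.

Supporting stages: low-expression filtering (mean FPKM < 0.1 in both
classes), a Welch-t + BH DEG baseline (FC > 2, FDR < 0.01), a
two-assessment correlation filter that prunes PPI edges unsupported by
expression, DGM-vs-DEG evaluation (sigmoid-kernel SVM 3-fold AUC,
hierarchical-clustering purity, hypergeometric GMT enrichment), and a
synthetic-data generator with planted ground truth so the whole pipeline
is testable without controlled-access cohort data.

## Worked example

Simulate a 100-gene study with three planted driver-gated modules, then
run the full pipeline:

```bash
netmod simulate --genes 100 --modules 3 --with-drivers --tumors 50 \
    --normals 50 --seed 1 --out-dir sim/
netmod run-all --expr sim/expression.tsv --labels sim/labels.tsv \
    --ppi sim/ppi.tsv --mut sim/mutations.tsv --gmt sim/sets.gmt \
    --perms 1000 --seed 1 --out-dir run/
python -m json.tool run/summary.json
```

This run printed (abridged from `summary.json`):

```
"n_genes_after_filter": 100,
"n_edges_input": 196,  "n_edges_retained": 196,
"n_modules": 79,       "n_dgms": 13,
"dgm_auc": 0.866,      "deg_auc": null,
"n_links": 15,         "n_linked_dgms": 13
```

Read: of 79 deduplicated greedy modules, 13 cleared the activity-score
and triple-permutation thresholds. Because the planted signal is
driver-gated — each module shifts only in the ~30% of tumors carrying
its driver mutation — not a single gene clears the FC > 2, FDR < 0.01
DEG baseline (`deg_auc` is null), yet module-average features still
classify tumor vs. normal at a pooled 3-fold AUC of 0.866: exactly the
situation module-level analysis exists for. All 13 DGMs were linked to
at least one mutated gene at FDR < 10⁻⁴ (15 module–driver links; two of
the three planted drivers are recovered, no passenger gene is linked).
`run/` also contains every
intermediate artifact (`norm.tsv`, `deg.tsv`, `filtered_ppi.tsv`,
`modules.tsv`, `dgms.tsv`, `links.tsv`, driver tables) plus a manifest
recording thresholds and seed; rerunning with the same seed reproduces
`summary.json` byte for byte.

The same stages are available as a library (`netmod.modules.grow_module`,
`netmod.significance.score_module_significance`,
`netmod.eqtl.eqtl_scan`, ...) and as individual subcommands
(`preprocess`, `filter-ppi`, `find-modules`, `significance`, `eqtl`,
`evaluate`).

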