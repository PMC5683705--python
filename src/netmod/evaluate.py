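"""Module-feature evaluation: classification, clustering, enrichment.

Module features are the per-sample averages of member Z-scores ("module
expression"); the single-gene comparator uses DEG Z-score rows directly.
Classification is a sigmoid-kernel SVM under stratified k-fold (default
3) with the AUC computed on pooled out-of-fold decision values.
Clustering is average-linkage agglomerative on Euclidean distances, cut
at two clusters, scored by the misclustered-sample count. Enrichment is
the upper-tail hypergeometric test against a GMT collection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import DataError
from .io import (GeneModule, GeneSetCollection, NormalizedExpressionMatrix,
                 PhenotypeLabels)
from .modules import module_expression

logger = logging.getLogger(__name__)

__all__ = ["FeatureMatrix", "module_feature_matrix", "gene_feature_matrix",
           "crossval_auc", "cluster_purity", "hypergeometric_enrichment",
           "shared_process_counts"]


@dataclass
class FeatureMatrix:
    """Samples x features real matrix with identifiers."""

    sample_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]
    values: np.ndarray  # (n_samples, n_features)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise DataError("feature matrix shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise DataError("feature values must be finite")


def module_feature_matrix(dgms: list[GeneModule],
                          norm: NormalizedExpressionMatrix) -> FeatureMatrix:
    """One feature per module: mean member Z-score per sample."""
    if not dgms:
        raise DataError("no modules to build features from")
    cols = np.stack([module_expression(m.members, norm) for m in dgms], axis=1)
    return FeatureMatrix(norm.sample_ids, tuple(m.seed for m in dgms), cols)


def gene_feature_matrix(genes: list[str],
                        norm: NormalizedExpressionMatrix) -> FeatureMatrix:
    """Single-gene features (the DEG comparator): Z-score rows, transposed."""
    if not genes:
        raise DataError("no genes to build features from")
    idx = norm.gene_index(genes)
    if (idx < 0).any():
        raise DataError("feature gene absent from expression")
    return FeatureMatrix(norm.sample_ids, tuple(genes), norm.values[idx].T)


def crossval_auc(features: FeatureMatrix, labels: PhenotypeLabels,
                 folds: int = 3, rng_seed: int = 0,
                 return_folds: bool = False):
    """Stratified k-fold sigmoid-kernel SVM; AUC of pooled decision values.

    Features are standardized per column inside each training fold (the
    sigmoid kernel is scale-sensitive). Deterministic for a fixed seed.
    """
    y = labels.aligned_to(features.sample_ids)
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise DataError(f"each class needs >= {folds} samples for {folds}-fold CV")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rng_seed)
    decision = np.empty(y.shape[0])
    fold_aucs = []
    for train, test in skf.split(features.values, y):
        clf = make_pipeline(StandardScaler(), SVC(kernel="sigmoid"))
        clf.fit(features.values[train], y[train])
        d = clf.decision_function(features.values[test])
        decision[test] = d
        if len(np.unique(y[test])) == 2:
            fold_aucs.append(float(roc_auc_score(y[test], d)))
    auc = float(roc_auc_score(y, decision))
    if return_folds:
        return auc, fold_aucs
    return auc


def cluster_purity(features: FeatureMatrix, labels: PhenotypeLabels) -> int:
    """Misclustered-sample count from a 2-cluster average-linkage cut.

    The two clusters are matched to the two classes in whichever of the
    two assignments agrees with more samples; the remainder is returned.
    """
    y = labels.aligned_to(features.sample_ids)
    if features.values.shape[0] < 2:
        raise DataError("clustering needs at least 2 samples")
    model = AgglomerativeClustering(n_clusters=2, linkage="average",
                                    metric="euclidean")
    c = model.fit_predict(features.values)
    agree = int(np.maximum((c == y).sum(), (c == 1 - y).sum()))
    return int(y.shape[0] - agree)


def hypergeometric_enrichment(members: list[str], sets: GeneSetCollection,
                              universe: list[str],
                              p_max: float = 0.01) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a gene list per term.

    For each term: population = |universe|, successes = |term ∩ universe|,
    draws = |members|, observed = |members ∩ term ∩ universe|; the p-value
    is P(X >= observed), which is 1 when the overlap is 0.
    """
    uni = set(universe)
    if not uni:
        raise DataError("empty enrichment universe")
    mem = set(members) & uni
    if set(members) - uni:
        raise DataError("module members must be contained in the universe")
    rows = []
    for term, genes in sorted(sets.items()):
        term_genes = set(genes) & uni
        k = len(mem & term_genes)
        if k == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(k - 1, len(uni), len(term_genes), len(mem)))
        rows.append((term, k, len(term_genes), p, p < p_max))
    return pd.DataFrame(rows, columns=["term", "overlap", "term_size",
                                       "p_value", "enriched"])


def shared_process_counts(dgms: list[GeneModule], sets: GeneSetCollection,
                          universe: list[str],
                          p_max: float = 0.01) -> dict[str, float]:
    """Fractions of modules with >= 2, 3, 4 members in one enriched term.

    For each module, take the largest overlap among its significantly
    enriched terms; aggregate the fractions of modules reaching each
    threshold. Modules with no enriched term count toward none.
    """
    best_overlap = []
    for m in dgms:
        table = hypergeometric_enrichment(list(m.members), sets, universe, p_max)
        enr = table[table["enriched"]]
        best_overlap.append(int(enr["overlap"].max()) if len(enr) else 0)
    best = np.asarray(best_overlap)
    n = max(len(dgms), 1)
    return {"frac_ge2": float((best >= 2).sum() / n),
            "frac_ge3": float((best >= 3).sum() / n),
            "frac_ge4": float((best >= 4).sum() / n)}
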