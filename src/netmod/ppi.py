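"""Expression-support filter for protein-interaction edges.

Each retained edge gets two correlation assessments: the Pearson
correlation of its endpoints across all samples, and the difference
between the tumor-only and normal-only correlations. Edges that rank in
the bottom fraction of BOTH assessments (by absolute value) are pruned —
interactions with neither overall co-expression nor a disease-dependent
co-expression change carry no expression support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DataError
from .io import ExpressionMatrix, PPINetwork, PhenotypeLabels

logger = logging.getLogger(__name__)

__all__ = ["EdgeScore", "score_edges", "filter_low_correlation_edges"]


@dataclass(frozen=True)
class EdgeScore:
    edge: tuple[str, str]
    corr_all: float
    delta_corr: float  # corr(tumor) - corr(normal)


def _rowwise_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation of paired rows; constant rows give 0, not NaN."""
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    na = np.sqrt((a * a).sum(axis=1))
    nb = np.sqrt((b * b).sum(axis=1))
    denom = na * nb
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a * b).sum(axis=1) / denom
    r = np.where(denom == 0, 0.0, r)
    return np.clip(r, -1.0, 1.0)


def score_edges(net: PPINetwork, expr: ExpressionMatrix,
                labels: PhenotypeLabels) -> list[EdgeScore]:
    """Correlation assessments for every edge with both endpoints in ``expr``.

    Edges with a missing endpoint are dropped (logged count). Each class
    must have at least 3 samples for a usable within-class correlation.
    Constant-expression endpoints score 0 with a warning.
    """
    y = labels.aligned_to(expr.sample_ids)
    tumor, normal = y == 1, y == 0
    if tumor.sum() < 3 or normal.sum() < 3:
        raise DataError("each class needs >= 3 samples for edge correlations")
    edges = sorted(net.edges)
    present = [(a, b) for a, b in edges if a in expr and b in expr]
    if len(present) < len(edges):
        logger.info("dropped %d edge(s) with endpoint missing from expression",
                    len(edges) - len(present))
    if not present:
        return []
    ia = expr.gene_index([a for a, _ in present])
    ib = expr.gene_index([b for _, b in present])
    va, vb = expr.values[ia], expr.values[ib]
    corr_all = _rowwise_corr(va, vb)
    corr_t = _rowwise_corr(va[:, tumor], vb[:, tumor])
    corr_n = _rowwise_corr(va[:, normal], vb[:, normal])
    n_const = int(((va.std(axis=1) == 0) | (vb.std(axis=1) == 0)).sum())
    if n_const:
        logger.warning("%d edge(s) with a constant endpoint scored 0", n_const)
    return [EdgeScore(e, float(ca), float(dt - dn))
            for e, ca, dt, dn in zip(present, corr_all, corr_t, corr_n)]


def filter_low_correlation_edges(scores: list[EdgeScore],
                                 percentile: float = 0.05) -> PPINetwork:
    """Remove edges ranking in the bottom ``percentile`` fraction of BOTH
    the |corr_all| and the |delta_corr| orderings (ascending).

    Ties are broken by lexicographic edge label so the result does not
    depend on input order. At most ``floor(percentile * m)`` edges can be
    removed (the intersection bound).
    """
    if not 0 < percentile < 1:
        raise ConfigError(f"percentile must be in (0, 1), got {percentile}")
    if not scores:
        raise DataError("no edge scores to filter")
    m = len(scores)
    k = int(np.floor(percentile * m))
    order_all = sorted(range(m), key=lambda i: (abs(scores[i].corr_all),
                                                scores[i].edge))
    order_delta = sorted(range(m), key=lambda i: (abs(scores[i].delta_corr),
                                                  scores[i].edge))
    bottom_all = set(order_all[:k])
    bottom_delta = set(order_delta[:k])
    removed = bottom_all & bottom_delta
    if removed:
        logger.info("removed %d of %d edges unsupported by either assessment",
                    len(removed), m)
    kept = frozenset(scores[i].edge for i in range(m) if i not in removed)
    return PPINetwork(kept)
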