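"""Mutual-information activity score and greedy module growth.

A module's expression X is the per-sample mean of its members' Z-scores.
The activity score AS is the empirical mutual information, in bits,
between the equal-width-discretized X and the binary phenotype Y:

    AS = sum_k sum_y p(k, y) * log2( p(k, y) / (p(k) p(y)) )

with 0 * log(0) = 0 and probabilities taken as empirical frequencies.
Growth starts from a seed gene and, at each step, scores every network
neighbor of the current member set by the AS of the enlarged module;
the best candidate is added only if it strictly improves the score.
Binning is recomputed from the candidate module's own X range at every
evaluation, since the range of the module average changes as it grows.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .errors import ConfigError, DataError
from .io import (ExpressionMatrix, GeneModule, NormalizedExpressionMatrix,
                 PPINetwork, PhenotypeLabels)

logger = logging.getLogger(__name__)

__all__ = ["default_bins", "module_expression", "discretize", "activity_score",
           "grow_module", "build_module_set", "coexpression_fraction"]


def default_bins(n_samples: int, cap: int = 10) -> int:
    """Sturges' rule, floor(log2(n) + 1), capped; never below 2."""
    return max(2, min(cap, int(np.floor(np.log2(n_samples) + 1))))


def module_expression(members: Sequence[str],
                      norm: NormalizedExpressionMatrix) -> np.ndarray:
    """Per-sample mean of the member genes' Z-score rows."""
    if not members:
        raise DataError("module has no members")
    idx = norm.gene_index(members)
    if (idx < 0).any():
        missing = members[int(np.argmax(idx < 0))]
        raise DataError(f"module member {missing!r} absent from expression")
    return norm.values[idx].mean(axis=0)


def discretize(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width bin labels (0-based) over [min(x), max(x)].

    Intervals are half-open [s_k, s_{k+1}) with the final bin closed, so a
    value exactly at a split point falls in the higher bin and max(x) in
    the last bin. A constant vector maps to bin 0 for every sample.
    """
    if n_bins < 2:
        raise ConfigError(f"n_bins must be >= 2, got {n_bins}")
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros(x.shape[0], dtype=np.intp)
    width = (hi - lo) / n_bins
    b = np.floor((x - lo) / width).astype(np.intp)
    return np.clip(b, 0, n_bins - 1)


def _mi_bits(counts: np.ndarray) -> float:
    """Mutual information (bits) from a joint count table (bins x classes)."""
    n = counts.sum()
    p = counts / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    terms = np.zeros_like(p)
    terms[nz] = p[nz] * np.log2(p[nz] / (px @ py)[nz])
    return float(max(terms.sum(), 0.0))


def activity_score(x: np.ndarray, y: np.ndarray, n_bins: int) -> float:
    """Empirical MI (bits) between binned ``x`` and binary labels ``y``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    if x.shape != y.shape:
        raise DataError(f"length mismatch: x has {x.shape[0]}, y has {y.shape[0]}")
    b = discretize(x, n_bins)
    counts = np.bincount(b * 2 + y, minlength=n_bins * 2).reshape(n_bins, 2)
    return _mi_bits(counts)


def _batch_activity(X: np.ndarray, y: np.ndarray, n_bins: int) -> np.ndarray:
    """Activity score of each row of ``X`` (vectorized over rows).

    Each row is binned over its own range, matching :func:`activity_score`.
    """
    X = np.asarray(X, dtype=float)
    m, n = X.shape
    lo = X.min(axis=1, keepdims=True)
    hi = X.max(axis=1, keepdims=True)
    width = (hi - lo) / n_bins
    safe = np.where(width == 0, 1.0, width)
    b = np.clip(np.floor((X - lo) / safe).astype(np.intp), 0, n_bins - 1)
    b[(hi == lo)[:, 0]] = 0
    flat = (np.arange(m)[:, None] * (n_bins * 2) + b * 2 + y[None, :]).ravel()
    counts = np.bincount(flat, minlength=m * n_bins * 2).astype(float)
    p = counts.reshape(m, n_bins, 2) / n
    px = p.sum(axis=2, keepdims=True)
    py = p.sum(axis=1, keepdims=True)
    denom = px * py
    nz = p > 0
    terms = np.zeros_like(p)
    terms[nz] = p[nz] * np.log2(p[nz] / denom[nz])
    return np.maximum(terms.sum(axis=(1, 2)), 0.0)


def grow_module(seed: str, net: PPINetwork, norm: NormalizedExpressionMatrix,
                labels: PhenotypeLabels, n_bins: int | None = None,
                max_size: int = 20) -> GeneModule:
    """Greedy seed expansion maximizing the activity score.

    Stops when no neighbor strictly improves the score, neighbors are
    exhausted, or ``max_size`` is reached. Candidate ties break toward the
    lexicographically smallest gene symbol.
    """
    if seed not in norm:
        raise DataError(f"seed gene {seed!r} absent from expression")
    y = labels.aligned_to(norm.sample_ids)
    if n_bins is None:
        n_bins = default_bins(norm.n_samples)
    graph = net.to_networkx()
    members = [seed]
    member_set = {seed}
    z_sum = norm.gene_row(seed).astype(float).copy()
    current = activity_score(z_sum, y, n_bins)
    while len(members) < max_size:
        cands = sorted({nbr for m in members if m in graph for nbr in graph[m]
                        if nbr not in member_set and nbr in norm})
        if not cands:
            break
        idx = norm.gene_index(cands)
        X = (z_sum[None, :] + norm.values[idx]) / (len(members) + 1)
        scores = _batch_activity(X, y, n_bins)
        best = int(np.argmax(scores))  # argmax keeps first = lexicographic min
        if scores[best] <= current:
            break
        members.append(cands[best])
        member_set.add(cands[best])
        z_sum += norm.values[idx[best]]
        current = float(scores[best])
    return GeneModule(seed, tuple(members), current)


def build_module_set(net: PPINetwork, norm: NormalizedExpressionMatrix,
                     labels: PhenotypeLabels, n_bins: int | None = None,
                     max_size: int = 20) -> list[GeneModule]:
    """Grow one module per gene present in both the network and expression.

    Exact-duplicate member sets are collapsed, keeping the record with the
    highest activity score (ties toward the smallest seed symbol). The
    result is sorted by descending score, then seed, and is invariant to
    gene input order.
    """
    seeds = sorted(net.nodes & frozenset(norm.gene_ids))
    best: dict[frozenset[str], GeneModule] = {}
    for k, seed in enumerate(seeds):
        mod = grow_module(seed, net, norm, labels, n_bins, max_size)
        key = frozenset(mod.members)
        kept = best.get(key)
        if (kept is None or mod.activity_score > kept.activity_score
                or (mod.activity_score == kept.activity_score
                    and mod.seed < kept.seed)):
            best[key] = mod
        if (k + 1) % 500 == 0:
            logger.info("grown %d/%d modules", k + 1, len(seeds))
    return sorted(best.values(), key=lambda m: (-m.activity_score, m.seed))


def coexpression_fraction(module: GeneModule, expr: ExpressionMatrix,
                          r_min: float = 0.3) -> float:
    """Fraction of member pairs with Pearson correlation >= ``r_min``.

    A module is called co-expressed when this fraction exceeds 0.5.
    Singleton modules return 1 with a warning (no pairs to assess).
    """
    if module.size < 2:
        logger.warning("coexpression_fraction on singleton module %s", module.seed)
        return 1.0
    idx = norm_idx = [i for i in expr.gene_index(module.members)]
    if any(i < 0 for i in norm_idx):
        raise DataError("module member absent from expression")
    rows = expr.values[idx]
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(rows)
    r = np.nan_to_num(r, nan=0.0)
    iu = np.triu_indices(module.size, k=1)
    return float((r[iu] >= r_min).mean())
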