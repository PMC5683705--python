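"""Expression filtering, Z-score normalization and the DEG baseline.

The differential-expression baseline flags a gene when it clears both a
fold-change and a Benjamini-Hochberg FDR cutoff simultaneously
(default FC > 2 and FDR < 0.01); it is the single-gene comparator the
module features are evaluated against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DataError
from .io import ExpressionMatrix, NormalizedExpressionMatrix, PhenotypeLabels

logger = logging.getLogger(__name__)

__all__ = ["DEGRecord", "filter_low_expression", "zscore_normalize",
           "detect_deg", "bh_adjust"]


@dataclass
class DEGRecord:
    """Per-gene differential-expression result.

    ``fold_change`` is the linear-scale tumor/normal mean ratio with a
    pseudocount of 1 in numerator and denominator.
    """

    gene_id: str
    fold_change: float
    p_value: float
    fdr: float
    significant: bool


def _split_classes(expr: ExpressionMatrix, labels: PhenotypeLabels):
    y = labels.aligned_to(expr.sample_ids)
    tumor = y == 1
    normal = y == 0
    if tumor.sum() == 0 or normal.sum() == 0:
        raise ConfigError("both tumor and normal samples are required")
    return tumor, normal


def filter_low_expression(expr: ExpressionMatrix, labels: PhenotypeLabels,
                          threshold: float = 0.1) -> ExpressionMatrix:
    """Drop genes whose mean expression is below ``threshold`` in tumor
    samples *as well as* normal samples (both-low rule); the sample set is
    unchanged. Idempotent."""
    tumor, normal = _split_classes(expr, labels)
    mean_t = expr.values[:, tumor].mean(axis=1)
    mean_n = expr.values[:, normal].mean(axis=1)
    keep = (mean_t >= threshold) | (mean_n >= threshold)
    removed = int((~keep).sum())
    if removed:
        logger.info("filter_low_expression removed %d of %d genes "
                    "(mean < %g in both classes)", removed, expr.n_genes, threshold)
    kept_genes = [g for g, k in zip(expr.gene_ids, keep) if k]
    return ExpressionMatrix(tuple(kept_genes), expr.sample_ids, expr.values[keep])


def zscore_normalize(expr: ExpressionMatrix) -> NormalizedExpressionMatrix:
    """Per-gene Z-score across all samples, sample (n-1) standard deviation.

    Constant genes map to all-zero rows with a logged warning so that
    flat-expression interactors remain usable as module members.
    """
    if expr.n_samples < 2:
        raise DataError("Z-score normalization needs at least 2 samples")
    mean = expr.values.mean(axis=1, keepdims=True)
    sd = expr.values.std(axis=1, ddof=1, keepdims=True)
    constant = sd[:, 0] == 0
    if constant.any():
        logger.warning("%d constant gene(s) normalized to all-zero rows",
                       int(constant.sum()))
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (expr.values - mean) / sd_safe
    z[constant] = 0.0
    return ExpressionMatrix(expr.gene_ids, expr.sample_ids, z)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped to 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def detect_deg(expr: ExpressionMatrix, labels: PhenotypeLabels,
               fc_min: float = 2.0, fdr_max: float = 0.01) -> list[DEGRecord]:
    """Welch t-test on log2(x+1) expression + BH correction, per gene.

    A gene is significant iff |log2 FC| > log2(fc_min) AND fdr < fdr_max,
    with FC the linear-scale (mean_tumor + 1)/(mean_normal + 1) ratio.

    Matrices containing negative values (log-intensity style data) are tested
    on the raw scale; the fold change then uses class means shifted to be
    non-negative so the ratio stays interpretable.
    """
    tumor, normal = _split_classes(expr, labels)
    if tumor.sum() < 2 or normal.sum() < 2:
        raise DataError("each class needs at least 2 samples for the t-test")
    if (expr.values < 0).any():
        logx = expr.values  # already log-like
    else:
        logx = np.log2(expr.values + 1.0)
    t_stat, pvals = stats.ttest_ind(logx[:, tumor], logx[:, normal],
                                    axis=1, equal_var=False)
    # genes constant in both classes have undefined t; treat as null
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    fdr = bh_adjust(pvals)
    mean_t = expr.values[:, tumor].mean(axis=1)
    mean_n = expr.values[:, normal].mean(axis=1)
    shift = min(0.0, float(min(mean_t.min(), mean_n.min())))
    fc = (mean_t - shift + 1.0) / (mean_n - shift + 1.0)
    sig = (np.abs(np.log2(fc)) > np.log2(fc_min)) & (fdr < fdr_max)
    return [DEGRecord(g, float(fc[i]), float(pvals[i]), float(fdr[i]), bool(sig[i]))
            for i, g in enumerate(expr.gene_ids)]
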