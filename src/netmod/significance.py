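"""Permutation nulls and the differential-gene-module selection rule.

Three nulls back each module: (1) phenotype permutation — shuffle the
tumor/normal labels and rescore the fixed member set; (2) random gene
sets of the same size; (3) random gene sets of the same size forced to
contain the seed. All p-values use the add-one tail estimator
p = (1 + #{null >= observed}) / (1 + n_perm), so p is never exactly 0.
A module is selected as a DGM when its activity score clears ``as_min``
(default 0.34) and every one of the three p-values is below ``p_max``
(default 0.001).

Note the nulls rescore the module as built; they do not rerun the greedy
search under the null, so the phenotype-permutation p carries the usual
selection-induced optimism.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DataError
from .io import GeneModule, NormalizedExpressionMatrix, PPINetwork, PhenotypeLabels
from .modules import _batch_activity, activity_score, default_bins, module_expression

__all__ = ["NullDistribution", "module_rng", "phenotype_permutation_pvalue",
           "random_geneset_pvalue", "score_module_significance", "select_dgms"]


@dataclass
class NullDistribution:
    kind: str  # phenotype_permutation | random_genes | random_genes_same_seed
    scores: np.ndarray
    n_permutations: int


def module_rng(master_seed: int, seed_gene: str) -> np.random.Generator:
    """Deterministic per-module stream: hash the seed gene into the spawn key.

    Keeps results reproducible and order-independent when modules are
    scored in parallel or in any order.
    """
    h = zlib.crc32(seed_gene.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(master_seed) % (2**31), h]))


def _add_one_p(null_scores: np.ndarray, observed: float) -> float:
    n = null_scores.shape[0]
    return float((1 + int((null_scores >= observed).sum())) / (1 + n))


def phenotype_permutation_pvalue(module: GeneModule,
                                 norm: NormalizedExpressionMatrix,
                                 labels: PhenotypeLabels,
                                 n_bins: int | None = None,
                                 n_perm: int = 1000,
                                 rng: np.random.Generator | int = 0,
                                 return_null: bool = False):
    """Tail p-value of the module's AS under label shuffling.

    Class counts are preserved exactly (permutation, not resampling); the
    member set stays fixed and only the labels move.
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    y = labels.aligned_to(norm.sample_ids)
    if n_bins is None:
        n_bins = default_bins(norm.n_samples)
    x = module_expression(module.members, norm)
    observed = activity_score(x, y, n_bins)
    perms = np.array([rng.permutation(y) for _ in range(n_perm)])
    # x (hence its binning) is fixed; only the labels move across the nulls
    null_scores = _null_scores_fixed_x(x, perms, n_bins)
    p = _add_one_p(null_scores, observed)
    if return_null:
        return p, NullDistribution("phenotype_permutation", null_scores, n_perm)
    return p


def _null_scores_fixed_x(x: np.ndarray, perms: np.ndarray, n_bins: int) -> np.ndarray:
    """AS of a fixed vector against many label permutations, vectorized."""
    from .modules import discretize, _mi_bits

    b = discretize(x, n_bins)
    onehot = np.zeros((x.shape[0], n_bins))
    onehot[np.arange(x.shape[0]), b] = 1.0
    bin_totals = onehot.sum(axis=0)  # invariant under permutation
    counts1 = perms.astype(float) @ onehot  # (n_perm, n_bins)
    counts0 = bin_totals[None, :] - counts1
    counts = np.stack([counts0, counts1], axis=2)  # (n_perm, n_bins, 2)
    n = x.shape[0]
    p = counts / n
    px = p.sum(axis=2, keepdims=True)
    py = p.sum(axis=1, keepdims=True)
    nz = p > 0
    terms = np.zeros_like(p)
    terms[nz] = p[nz] * np.log2(p[nz] / (px * py)[nz])
    return np.maximum(terms.sum(axis=(1, 2)), 0.0)


def random_geneset_pvalue(module: GeneModule,
                          norm: NormalizedExpressionMatrix,
                          labels: PhenotypeLabels,
                          net: PPINetwork | None = None,
                          keep_seed: bool = False,
                          n_bins: int | None = None,
                          n_perm: int = 1000,
                          rng: np.random.Generator | int = 0,
                          return_null: bool = False):
    """Tail p-value of the module's AS against same-size random gene sets.

    Draws ignore network connectivity; with ``keep_seed`` the seed gene is
    forced into every draw and only the remaining members are resampled.
    The true labels are used throughout.
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    y = labels.aligned_to(norm.sample_ids)
    if n_bins is None:
        n_bins = default_bins(norm.n_samples)
    k = module.size
    universe = np.arange(norm.n_genes)
    seed_idx = int(norm.gene_index([module.seed])[0])
    if keep_seed:
        universe = universe[universe != seed_idx]
        n_draw = k - 1
    else:
        n_draw = k
    if n_draw > universe.shape[0]:
        raise DataError("module larger than the gene universe")
    x_obs = module_expression(module.members, norm)
    observed = activity_score(x_obs, y, n_bins)
    if n_draw == 0:
        X = np.broadcast_to(norm.values[seed_idx], (n_perm, norm.n_samples)).copy()
    else:
        draws = np.array([rng.choice(universe, size=n_draw, replace=False)
                          for _ in range(n_perm)])
        X = norm.values[draws].sum(axis=1)
        if keep_seed:
            X = X + norm.values[seed_idx][None, :]
        X = X / k
    null_scores = _batch_activity(X, y, n_bins)
    p = _add_one_p(null_scores, observed)
    kind = "random_genes_same_seed" if keep_seed else "random_genes"
    if return_null:
        return p, NullDistribution(kind, null_scores, n_perm)
    return p


def score_module_significance(modules: list[GeneModule],
                              norm: NormalizedExpressionMatrix,
                              labels: PhenotypeLabels,
                              net: PPINetwork | None = None,
                              n_bins: int | None = None,
                              n_perm: int = 1000,
                              master_seed: int = 0) -> list[GeneModule]:
    """Attach all three permutation p-values to each module.

    Each module gets its own RNG stream derived from (master_seed, seed
    gene), so results do not depend on evaluation order.
    """
    out = []
    for m in modules:
        rng = module_rng(master_seed, m.seed)
        p_phen = phenotype_permutation_pvalue(m, norm, labels, n_bins, n_perm, rng)
        p_rand = random_geneset_pvalue(m, norm, labels, net, keep_seed=False,
                                       n_bins=n_bins, n_perm=n_perm, rng=rng)
        p_seed = random_geneset_pvalue(m, norm, labels, net, keep_seed=True,
                                       n_bins=n_bins, n_perm=n_perm, rng=rng)
        out.append(GeneModule(m.seed, m.members, m.activity_score,
                              p_phen, p_rand, p_seed))
    return out


def select_dgms(modules: list[GeneModule], as_min: float = 0.34,
                p_max: float = 0.001) -> list[GeneModule]:
    """Keep modules with AS >= ``as_min`` and all three p-values < ``p_max``."""
    out = []
    for m in modules:
        if any(p is None for p in m.pvalues):
            raise DataError(f"module {m.seed!r} is missing a permutation p-value")
        if m.activity_score >= as_min and all(p < p_max for p in m.pvalues):
            out.append(m)
    return out
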