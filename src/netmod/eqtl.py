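"""Module-level eQTL: link somatic mutations to differential gene modules.

Stage two of the method. Each (mutated gene, expression gene) pair is
tested by simple linear regression of the gene's Z-scored expression on
the binary mutation status across tumor samples; p-values come from the
two-sided t-test on the slope and are BH-adjusted once across the whole
scan. A mutated gene is linked to a module when ANY member gene clears
the FDR cutoff (default 1e-4). For a binary predictor the regression
t-test is algebraically the pooled-variance two-sample t-test, which the
test suite exploits as an independent cross-check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .io import (GeneModule, MutationMatrix, NormalizedExpressionMatrix,
                 PhenotypeLabels)
from .preprocess import bh_adjust

logger = logging.getLogger(__name__)

__all__ = ["ModuleMutationLink", "eqtl_scan", "link_mutations_to_modules",
           "driver_summary", "mutual_exclusivity_test"]

#: Column contract of the association table returned by :func:`eqtl_scan`.
ASSOCIATION_COLUMNS = ["mutated_gene", "expression_gene", "beta", "p_value", "fdr"]


@dataclass
class ModuleMutationLink:
    module_seed: str
    mutated_gene: str
    supporting_members: tuple[str, ...]
    min_fdr: float


def eqtl_scan(mut: MutationMatrix, norm: NormalizedExpressionMatrix,
              genes: list[str] | None = None,
              labels: PhenotypeLabels | None = None,
              min_mutated: int = 3) -> pd.DataFrame:
    """Regression scan of every (mutated gene, expression gene) pair.

    Runs over the samples shared by both matrices; when ``labels`` is
    given the scan is restricted to tumor samples (somatic mutations are
    tumor properties — including normals would let any tumor-vs-normal DE
    gene masquerade as an eQTL target). Mutated genes altered in fewer
    than ``min_mutated`` shared samples, or in all of them, are skipped
    with a logged count. FDR is BH over all tested pairs jointly.
    """
    shared = [s for s in norm.sample_ids if s in set(mut.sample_ids)]
    if labels is not None:
        tumor = set(labels.tumor_samples)
        shared = [s for s in shared if s in tumor]
    if not shared:
        raise DataError("no shared samples between mutation and expression data")
    n = len(shared)
    if genes is None:
        genes = list(norm.gene_ids)
    else:
        missing = [g for g in genes if g not in norm]
        if missing:
            raise DataError(f"expression gene {missing[0]!r} not found")
    expr = norm.subset_samples(shared)
    e_idx = expr.gene_index(genes)
    E = expr.values[e_idx]  # (n_expr, n)
    mut_pos = {s: j for j, s in enumerate(mut.sample_ids)}
    s_cols = [mut_pos[s] for s in shared]
    records: list[pd.DataFrame] = []
    skipped = 0
    sum_e = E.sum(axis=1)
    sum_e2 = (E * E).sum(axis=1)
    for gi, g in enumerate(mut.gene_ids):
        s = mut.status[gi, s_cols].astype(float)
        n1 = int(s.sum())
        n0 = n - n1
        if n1 < min_mutated or n0 < 1 or n < 3:
            skipped += 1
            continue
        mean1 = (E @ s) / n1
        mean0 = (sum_e - mean1 * n1) / n0
        beta = mean1 - mean0  # slope of e ~ status
        # pooled residual variance of the simple regression
        ss_res = sum_e2 - n1 * mean1**2 - n0 * mean0**2
        sigma2 = ss_res / (n - 2)
        se = np.sqrt(np.maximum(sigma2, 0.0) * (1.0 / n1 + 1.0 / n0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta / se
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        p = np.where(np.isfinite(t), p, np.where(beta == 0, 1.0, 0.0))
        records.append(pd.DataFrame({"mutated_gene": g, "expression_gene": genes,
                                     "beta": beta, "p_value": p}))
    if skipped:
        logger.info("skipped %d mutated gene(s) below %d mutated samples",
                    skipped, min_mutated)
    if not records:
        return pd.DataFrame(columns=ASSOCIATION_COLUMNS)
    out = pd.concat(records, ignore_index=True)
    out["fdr"] = bh_adjust(out["p_value"].to_numpy())
    return out[ASSOCIATION_COLUMNS]


def link_mutations_to_modules(assocs: pd.DataFrame, dgms: list[GeneModule],
                              fdr_max: float = 1e-4) -> list[ModuleMutationLink]:
    """Any-member rule: link (module, mutated gene) when at least one
    member gene's association passes ``fdr < fdr_max``."""
    if assocs.empty:
        return []
    sig = assocs[assocs["fdr"] < fdr_max]
    links: list[ModuleMutationLink] = []
    for m in dgms:
        member_set = set(m.members)
        hits = sig[sig["expression_gene"].isin(member_set)]
        for mg, grp in hits.groupby("mutated_gene", sort=True):
            support = tuple(sorted(set(grp["expression_gene"])))
            links.append(ModuleMutationLink(m.seed, str(mg), support,
                                            float(grp["fdr"].min())))
    return links


def driver_summary(links: list[ModuleMutationLink], dgms: list[GeneModule]):
    """Roll links up into per-module and per-driver count tables.

    Returns ``(module_table, gene_table, histogram)``: mutated genes per
    module, modules per mutated gene (descending), and the number of
    modules having exactly k associated mutated genes.
    """
    per_module: dict[str, set[str]] = {m.seed: set() for m in dgms}
    per_gene: dict[str, set[str]] = {}
    for ln in links:
        per_module.setdefault(ln.module_seed, set()).add(ln.mutated_gene)
        per_gene.setdefault(ln.mutated_gene, set()).add(ln.module_seed)
    module_table = pd.DataFrame(
        [(seed, len(genes)) for seed, genes in sorted(per_module.items())],
        columns=["module", "n_mutated_genes"])
    gene_table = pd.DataFrame(
        sorted(((g, len(mods)) for g, mods in per_gene.items()),
               key=lambda t: (-t[1], t[0])),
        columns=["mutated_gene", "n_dgms"])
    linked = module_table[module_table["n_mutated_genes"] > 0]
    histogram = (linked.groupby("n_mutated_genes").size()
                 .rename("n_modules").reset_index())
    return module_table, gene_table, histogram


def mutual_exclusivity_test(mut: MutationMatrix, gene_a: str,
                            gene_b: str) -> tuple[float, float]:
    """Fisher's exact test for co-occurrence/exclusivity of two mutations.

    Returns (odds_ratio, two-sided p). The odds ratio uses the Haldane
    0.5 correction when any cell of the 2x2 table is empty; an odds ratio
    below 1 indicates mutual exclusivity.
    """
    a = mut.gene_row(gene_a).astype(bool)
    b = mut.gene_row(gene_b).astype(bool)
    table = np.array([[int((a & b).sum()), int((a & ~b).sum())],
                      [int((~a & b).sum()), int((~a & ~b).sum())]], dtype=float)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    if (table == 0).any():
        table = table + 0.5
    odds = float(table[0, 0] * table[1, 1] / (table[0, 1] * table[1, 0]))
    return odds, float(p)
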