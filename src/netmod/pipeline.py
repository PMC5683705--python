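"""End-to-end orchestration: preprocess -> edge filter -> module search ->
permutation significance -> module eQTL -> evaluation.

Every stage writes its artifact as a plain file into the run directory so
stages can be rerun independently; a manifest records the configuration
and seed, and ``summary.json`` collects the headline quantities. A rerun
with the same inputs, configuration and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .errors import ConfigError, DataError
from .eqtl import driver_summary, eqtl_scan, link_mutations_to_modules
from .evaluate import (cluster_purity, crossval_auc, gene_feature_matrix,
                       module_feature_matrix, shared_process_counts)
from .io import (read_edge_list, read_expression_matrix, read_gmt,
                 read_mutation_matrix, read_phenotype_labels, write_edge_list,
                 write_expression_matrix, write_module_set)
from .modules import build_module_set, coexpression_fraction
from .ppi import filter_low_correlation_edges, score_edges
from .preprocess import detect_deg, filter_low_expression, zscore_normalize
from .significance import score_module_significance, select_dgms

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Input paths plus every pipeline threshold, with the defaults the
    method prescribes. ``mut`` and ``gmt`` are optional stages."""

    expr: str
    labels: str
    ppi: str
    mut: str | None = None
    gmt: str | None = None
    min_expression: float = 0.1
    edge_percentile: float = 0.05
    n_bins: int | None = None      # None = Sturges' rule on the sample count
    max_size: int = 20
    n_perm: int = 1000
    as_min: float = 0.34
    p_max: float = 0.001
    eqtl_fdr: float = 1e-4
    fc_min: float = 2.0
    deg_fdr: float = 0.01
    min_mutated: int = 3
    folds: int = 3
    enrich_p: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.edge_percentile < 1:
            raise ConfigError("edge_percentile must be in (0, 1)")
        for name in ("p_max", "eqtl_fdr", "deg_fdr", "enrich_p"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigError(f"{name} must be in (0, 1], got {v}")
        if self.n_perm < 1 or self.max_size < 1 or self.folds < 2:
            raise ConfigError("n_perm/max_size/folds out of range")
        if self.as_min < 0 or self.fc_min <= 0:
            raise ConfigError("as_min must be >= 0 and fc_min > 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        if "expr" not in raw or "labels" not in raw or "ppi" not in raw:
            raise ConfigError("config must set expr, labels and ppi paths")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _round(x: float | None, nd: int = 10) -> float | None:
    return None if x is None else round(float(x), nd)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Run every stage, writing artifacts, a manifest and summary.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    expr = read_expression_matrix(config.expr)
    labels = read_phenotype_labels(config.labels)
    net = read_edge_list(config.ppi)
    mut = read_mutation_matrix(config.mut) if config.mut else None
    sets = read_gmt(config.gmt) if config.gmt else None

    # -- preprocess ---------------------------------------------------------
    filtered = filter_low_expression(expr, labels, config.min_expression)
    degs = detect_deg(filtered, labels, config.fc_min, config.deg_fdr)
    pd.DataFrame([dataclasses.asdict(d) for d in degs]).to_csv(
        out / "deg.tsv", sep="\t", index=False)
    norm = zscore_normalize(filtered)
    write_expression_matrix(norm, out / "norm.tsv")
    deg_genes = [d.gene_id for d in degs if d.significant]

    # -- PPI correlation filter --------------------------------------------
    scores = score_edges(net, filtered, labels)
    net_f = filter_low_correlation_edges(scores, config.edge_percentile)
    write_edge_list(net_f, out / "filtered_ppi.tsv")

    # -- module search + significance --------------------------------------
    modules = build_module_set(net_f, norm, labels, config.n_bins,
                               config.max_size)
    write_module_set(modules, out / "modules.tsv")
    scored = score_module_significance(modules, norm, labels, net_f,
                                       config.n_bins, config.n_perm,
                                       master_seed=config.seed)
    dgms = select_dgms(scored, config.as_min, config.p_max)
    write_module_set(dgms, out / "dgms.tsv")
    coexpr = [coexpression_fraction(m, norm) for m in dgms if m.size >= 2]

    summary: dict = {
        "netmod_version": __version__,
        "n_genes_input": expr.n_genes,
        "n_genes_after_filter": filtered.n_genes,
        "n_deg": len(deg_genes),
        "n_edges_input": len(net),
        "n_edges_retained": len(net_f),
        "n_modules": len(modules),
        "n_dgms": len(dgms),
        "median_dgm_size": (float(pd.Series([m.size for m in dgms]).median())
                            if dgms else None),
        "coexpressed_dgm_fraction": (_round(sum(f > 0.5 for f in coexpr)
                                            / len(coexpr)) if coexpr else None),
    }

    # -- module eQTL --------------------------------------------------------
    if mut is not None and dgms:
        member_union = sorted({g for m in dgms for g in m.members})
        assoc = eqtl_scan(mut, norm, member_union, labels, config.min_mutated)
        assoc.to_csv(out / "eqtl_associations.tsv", sep="\t", index=False)
        links = link_mutations_to_modules(assoc, dgms, config.eqtl_fdr)
        pd.DataFrame([{"module": ln.module_seed, "mutated_gene": ln.mutated_gene,
                       "supporting_members": ",".join(ln.supporting_members),
                       "min_fdr": ln.min_fdr} for ln in links]).to_csv(
            out / "links.tsv", sep="\t", index=False)
        module_table, gene_table, histogram = driver_summary(links, dgms)
        module_table.to_csv(out / "drivers_per_module.tsv", sep="\t", index=False)
        gene_table.to_csv(out / "dgms_per_driver.tsv", sep="\t", index=False)
        histogram.to_csv(out / "driver_histogram.tsv", sep="\t", index=False)
        summary["n_links"] = len(links)
        summary["n_linked_dgms"] = int((module_table["n_mutated_genes"] > 0).sum())
        summary["top_drivers"] = gene_table.head(10).to_dict("records")
    else:
        summary["n_links"] = None

    # -- evaluation ---------------------------------------------------------
    if dgms:
        feats = module_feature_matrix(dgms, norm)
        summary["dgm_auc"] = _round(crossval_auc(feats, labels, config.folds,
                                                 rng_seed=config.seed))
        summary["dgm_misclustered"] = cluster_purity(feats, labels)
    else:
        summary["dgm_auc"] = summary["dgm_misclustered"] = None
    if deg_genes:
        gfeats = gene_feature_matrix(deg_genes, norm)
        summary["deg_auc"] = _round(crossval_auc(gfeats, labels, config.folds,
                                                 rng_seed=config.seed))
        summary["deg_misclustered"] = cluster_purity(gfeats, labels)
    else:
        summary["deg_auc"] = summary["deg_misclustered"] = None
    if sets is not None and dgms:
        summary["shared_process"] = {
            k: _round(v) for k, v in shared_process_counts(
                dgms, sets, list(norm.gene_ids), config.enrich_p).items()}
    else:
        summary["shared_process"] = None

    manifest = {"netmod_version": __version__, "config": config.to_dict()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    (out / "summary.json").write_text(json.dumps(summary, indent=1,
                                                 sort_keys=True))
    logger.info("pipeline complete: %d modules, %d DGMs", len(modules), len(dgms))
    return out
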