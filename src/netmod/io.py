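"""Domain types and file I/O for every format the pipeline touches.

All tabular files are UTF-8, tab-delimited. Gene identity is the bare
symbol string, case-sensitive; joins across files are by exact symbol.
Gene sets use the standard GMT layout (term, description, genes...).
Missing expression values are not supported: readers fail fast.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ParseError

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "PhenotypeLabels",
    "PPINetwork",
    "MutationMatrix",
    "GeneModule",
    "GeneSetCollection",
    "read_expression_matrix",
    "read_phenotype_labels",
    "read_edge_list",
    "read_mutation_matrix",
    "mutation_matrix_from_pairs",
    "read_gmt",
    "write_gmt",
    "write_expression_matrix",
    "write_edge_list",
    "write_phenotype_labels",
    "write_mutation_matrix",
    "write_module_set",
    "read_module_set",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise DataError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Gene x sample real-valued expression (FPKM-like or log-intensity)."""

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray  # shape (n_genes, n_samples)

    def __post_init__(self) -> None:
        self.gene_ids = tuple(self.gene_ids)
        self.sample_ids = tuple(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise DataError("expression values must be finite")
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_row(self, gene: str) -> np.ndarray:
        try:
            return self.values[self._index[gene]]
        except KeyError:
            raise DataError(f"unknown gene: {gene!r}") from None

    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        return np.array([self._index[g] if g in self._index else -1 for g in genes])

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = [self._index[g] for g in genes]
        return replace(self, gene_ids=tuple(genes), values=self.values[idx])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in samples]
        return replace(self, sample_ids=tuple(samples), values=self.values[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids),
                            columns=list(self.sample_ids))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(tuple(map(str, df.index)), tuple(map(str, df.columns)),
                   df.to_numpy(dtype=float))


# A Z-scored ExpressionMatrix keeps the same container; preprocess documents
# the per-gene mean-0 / sd-1 contract.
NormalizedExpressionMatrix = ExpressionMatrix


@dataclass
class PhenotypeLabels:
    """Binary tissue phenotype per sample (tumor = 1, normal = 0)."""

    sample_ids: tuple[str, ...]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = tuple(self.sample_ids)
        self.labels = np.asarray(self.labels, dtype=int)
        _check_unique(self.sample_ids, "sample")
        if self.labels.shape != (len(self.sample_ids),):
            raise DataError("one label per sample required")
        if not np.isin(self.labels, [0, 1]).all():
            raise DataError("labels must be 0 (normal) or 1 (tumor)")
        self._index = {s: i for i, s in enumerate(self.sample_ids)}

    def aligned_to(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Label vector reordered to ``sample_ids``; errors on missing samples."""
        try:
            return self.labels[[self._index[s] for s in sample_ids]]
        except KeyError as e:
            raise DataError(f"sample without phenotype label: {e.args[0]!r}") from None

    @property
    def tumor_samples(self) -> tuple[str, ...]:
        return tuple(s for s, y in zip(self.sample_ids, self.labels) if y == 1)

    @property
    def normal_samples(self) -> tuple[str, ...]:
        return tuple(s for s, y in zip(self.sample_ids, self.labels) if y == 0)


def _canon_edge(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class PPINetwork:
    """Undirected protein-interaction network over gene-symbol nodes.

    Edges are unique unordered pairs; self-loops are disallowed.
    """

    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges",
                           frozenset(_canon_edge(*e) for e in self.edges))
        for a, b in self.edges:
            if a == b:
                raise DataError(f"self-loop edge not allowed: {a!r}")

    @classmethod
    def from_edges(cls, pairs: Iterable[tuple[str, str]],
                   drop_self_loops: bool = False) -> "PPINetwork":
        kept, dropped = set(), 0
        for a, b in pairs:
            if a == b:
                if not drop_self_loops:
                    raise DataError(f"self-loop edge not allowed: {a!r}")
                dropped += 1
                continue
            kept.add(_canon_edge(a, b))
        if dropped:
            logger.info("dropped %d self-loop edge(s)", dropped)
        return cls(frozenset(kept))

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(g for e in self.edges for g in e)

    def __len__(self) -> int:
        return len(self.edges)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_edges_from(self.edges)
        return g


@dataclass
class MutationMatrix:
    """Gene x sample binary somatic point-mutation status."""

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    status: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = tuple(self.gene_ids)
        self.sample_ids = tuple(self.sample_ids)
        self.status = np.asarray(self.status, dtype=int)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.status.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataError("mutation matrix shape mismatch")
        if not np.isin(self.status, [0, 1]).all():
            raise DataError("mutation status entries must be 0 or 1")
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    def gene_row(self, gene: str) -> np.ndarray:
        try:
            return self.status[self._index[gene]]
        except KeyError:
            raise DataError(f"unknown mutated gene: {gene!r}") from None

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.status, index=list(self.gene_ids),
                            columns=list(self.sample_ids))


@dataclass
class GeneModule:
    """A connected gene set grown greedily from a seed.

    ``members`` is the growth order (seed first); ``activity_score`` is the
    mutual information, in bits, between the discretized module-average
    expression and the phenotype. The three p-values come from the
    phenotype-permutation and the two random-gene-set nulls.
    """

    seed: str
    members: tuple[str, ...]
    activity_score: float
    pvalue_phenotype: float | None = None
    pvalue_random: float | None = None
    pvalue_random_seeded: float | None = None

    def __post_init__(self) -> None:
        self.members = tuple(self.members)
        if self.seed not in self.members:
            raise DataError(f"seed {self.seed!r} missing from members")
        _check_unique(self.members, "member gene")
        if self.activity_score < 0:
            raise DataError("activity score must be non-negative")

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def pvalues(self) -> tuple[float | None, float | None, float | None]:
        return (self.pvalue_phenotype, self.pvalue_random,
                self.pvalue_random_seeded)


@dataclass
class GeneSetCollection:
    """Annotation terms mapped to their (unique) gene lists."""

    sets: dict[str, tuple[str, ...]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, genes in self.sets.items():
            genes = tuple(genes)
            _check_unique(genes, f"gene in term {term!r}")
            self.sets[term] = genes

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, term: str) -> tuple[str, ...]:
        return self.sets[term]

    def items(self):
        return self.sets.items()


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_matrix_tsv(path: str | Path, what: str) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                         keep_default_na=False, na_values=[])
    except Exception as e:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: malformed {what} table: {e}") from e
    if df.columns.size == 0:
        raise ParseError(f"{path}: header row with sample identifiers required")
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ParseError(f"{path}: duplicate gene row {dup[0]!r}")
    dup_s = df.columns[df.columns.duplicated()]
    if len(dup_s):
        raise ParseError(f"{path}: duplicate sample column {dup_s[0]!r}")
    return df


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a gene x sample TSV (header = sample ids, first column = genes)."""
    df = _read_matrix_tsv(path, "expression")
    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            try:
                values[i, j] = float(raw[i, j])
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric cell {raw[i, j]!r} at gene "
                    f"{df.index[i]!r}, sample {df.columns[j]!r}"
                ) from None
    if not np.all(np.isfinite(values)):
        i, j = map(int, np.argwhere(~np.isfinite(values))[0])
        raise ParseError(f"{path}: non-finite value at gene {df.index[i]!r}, "
                         f"sample {df.columns[j]!r}")
    return ExpressionMatrix(tuple(df.index), tuple(df.columns), values)


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.to_frame().to_csv(path, sep="\t", index_label="gene")


def read_phenotype_labels(path: str | Path) -> PhenotypeLabels:
    """Read a two-column TSV ``sample<TAB>label`` with a header row."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected two columns (sample, label)")
    labels = []
    for k, v in enumerate(df.iloc[:, 1]):
        if v not in {"0", "1"}:
            raise ParseError(f"{path}: line {k + 2}: label must be 0 or 1, got {v!r}")
        labels.append(int(v))
    return PhenotypeLabels(tuple(df.iloc[:, 0]), np.array(labels))


def write_phenotype_labels(labels: PhenotypeLabels, path: str | Path) -> None:
    pd.DataFrame({"sample": list(labels.sample_ids),
                  "label": labels.labels}).to_csv(path, sep="\t", index=False)


def read_edge_list(path: str | Path) -> PPINetwork:
    """Read a two-column TSV of interacting gene symbols.

    Duplicate edges (in either orientation) are collapsed; self-loops are
    dropped with a logged count.
    """
    path = Path(path)
    pairs = []
    with open(path, encoding="utf-8") as fh:
        for k, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise ParseError(f"{path}: line {k}: expected two tab-separated "
                                 f"gene symbols, got {line!r}")
            pairs.append((parts[0], parts[1]))
    return PPINetwork.from_edges(pairs, drop_self_loops=True)


def write_edge_list(net: PPINetwork, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(net.edges):
            fh.write(f"{a}\t{b}\n")


def read_mutation_matrix(path: str | Path) -> MutationMatrix:
    """Read a gene x sample TSV of 0/1 somatic mutation calls."""
    df = _read_matrix_tsv(path, "mutation")
    raw = df.to_numpy()
    status = np.empty(df.shape, dtype=int)
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            v = raw[i, j]
            if v not in ("0", "1"):
                raise ParseError(f"{path}: entry {v!r} at gene {df.index[i]!r}, "
                                 f"sample {df.columns[j]!r} is not 0/1")
            status[i, j] = int(v)
    return MutationMatrix(tuple(df.index), tuple(df.columns), status)


def write_mutation_matrix(mut: MutationMatrix, path: str | Path) -> None:
    mut.to_frame().to_csv(path, sep="\t", index_label="gene")


def mutation_matrix_from_pairs(pairs: Iterable[tuple[str, str]],
                               sample_ids: Sequence[str]) -> MutationMatrix:
    """Build a binary matrix from MAF-like (gene, sample) mutation records.

    Any recorded pair sets status 1; samples never mentioned stay 0.
    """
    sample_ids = tuple(sample_ids)
    pos = {s: j for j, s in enumerate(sample_ids)}
    by_gene: dict[str, set[int]] = {}
    for gene, sample in pairs:
        if sample not in pos:
            raise DataError(f"mutation record for unknown sample {sample!r}")
        by_gene.setdefault(gene, set()).add(pos[sample])
    genes = tuple(sorted(by_gene))
    status = np.zeros((len(genes), len(sample_ids)), dtype=int)
    for i, g in enumerate(genes):
        status[i, sorted(by_gene[g])] = 1
    return MutationMatrix(genes, sample_ids, status)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets in GMT format (term, description, genes...)."""
    path = Path(path)
    sets: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for k, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: line {k}: GMT rows need term, "
                                 f"description and at least one gene")
            term, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if term in sets:
                raise ParseError(f"{path}: line {k}: duplicate term {term!r}")
            sets[term] = tuple(dict.fromkeys(genes))
            descriptions[term] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term, genes in sets.items():
            desc = sets.descriptions.get(term, "")
            fh.write("\t".join([term, desc, *genes]) + "\n")


_MODULE_COLUMNS = ["seed", "members", "activity_score", "pvalue_phenotype",
                   "pvalue_random", "pvalue_random_seeded"]


def write_module_set(modules: Sequence[GeneModule], path: str | Path) -> None:
    """Write modules as a TSV plus a JSON sidecar (``<path>.json``).

    The TSV is for human consumption; the sidecar keeps full float precision
    so that ``read_module_set(write_module_set(x)) == x``.
    """
    path = Path(path)
    rows = [{"seed": m.seed, "members": ",".join(m.members),
             "activity_score": m.activity_score,
             "pvalue_phenotype": m.pvalue_phenotype,
             "pvalue_random": m.pvalue_random,
             "pvalue_random_seeded": m.pvalue_random_seeded}
            for m in modules]
    pd.DataFrame(rows, columns=_MODULE_COLUMNS).to_csv(path, sep="\t", index=False)
    sidecar = [{"seed": m.seed, "members": list(m.members),
                "activity_score": m.activity_score,
                "pvalue_phenotype": m.pvalue_phenotype,
                "pvalue_random": m.pvalue_random,
                "pvalue_random_seeded": m.pvalue_random_seeded}
               for m in modules]
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_module_set(path: str | Path) -> list[GeneModule]:
    """Read modules written by :func:`write_module_set`.

    Prefers the JSON sidecar (lossless floats); falls back to the TSV.
    """
    path = Path(path)
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        records = json.loads(sidecar.read_text())
        return [GeneModule(r["seed"], tuple(r["members"]), r["activity_score"],
                           r["pvalue_phenotype"], r["pvalue_random"],
                           r["pvalue_random_seeded"]) for r in records]
    df = pd.read_csv(path, sep="\t", dtype={"seed": str, "members": str})
    out = []
    for _, r in df.iterrows():
        def _p(v):
            return None if pd.isna(v) else float(v)
        out.append(GeneModule(r["seed"], tuple(r["members"].split(",")),
                              float(r["activity_score"]),
                              _p(r["pvalue_phenotype"]), _p(r["pvalue_random"]),
                              _p(r["pvalue_random_seeded"])))
    return out
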