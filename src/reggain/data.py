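"""Expression-matrix and prior-network ingestion, preprocessing, and the hub
partition used by topology-aware augmentation.

Conventions
-----------
* Expression matrices are genes x cells; the gene universe of the prior
  network is exactly the gene universe of the expression matrix, so genes
  that are expressed but absent from the prior become isolated nodes.
* Normalization is per *gene*: each gene row is divided by its total count
  across cells, rescaled, and log1p-transformed.  Normalization happens
  before gene selection.
* The prior adjacency is binary and directed: ``A[i, j] = 1`` means gene i
  regulates gene j.  Self-loops are always dropped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

__all__ = [
    "GeneExpressionMatrix",
    "PriorNetwork",
    "GroundTruthNetwork",
    "load_expression",
    "load_tf_list",
    "load_edge_list",
    "load_ground_truth",
    "normalize_expression",
    "select_genes",
    "build_prior_graph",
    "identify_hubs",
]


@dataclass
class GeneExpressionMatrix:
    """A genes x cells non-negative expression matrix with identifiers."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        n, d = self.values.shape
        if n != len(self.gene_ids):
            raise ValueError(
                f"matrix has {n} rows but {len(self.gene_ids)} gene ids"
            )
        if d != len(self.cell_ids):
            raise ValueError(
                f"matrix has {d} columns but {len(self.cell_ids)} cell ids"
            )
        dupes = _duplicates(self.gene_ids)
        if dupes:
            raise ValueError(f"duplicate gene ids: {sorted(dupes)}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite entries")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}


@dataclass
class PriorNetwork:
    """Directed prior gene-interaction network over the expression genes.

    ``hub_nodes``/``hub_edges`` hold the high-centrality partition (Vs, Es)
    once :func:`identify_hubs` has run; ``rest_edges`` (Er) is every edge not
    in Es, including hub-to-non-hub edges.
    """

    gene_ids: list[str]
    edges: set[tuple[int, int]]
    hub_nodes: set[int] | None = None
    hub_edges: set[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-loop edge ({i}, {j}) in prior network")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"edge ({i}, {j}) out of range for {n} genes")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def rest_nodes(self) -> set[int] | None:
        if self.hub_nodes is None:
            return None
        return set(range(self.n_genes)) - self.hub_nodes

    @property
    def rest_edges(self) -> set[tuple[int, int]] | None:
        if self.hub_edges is None:
            return None
        return self.edges - self.hub_edges

    def adjacency(self) -> np.ndarray:
        """Dense binary adjacency A with A[i, j] = 1 iff i -> j."""
        a = np.zeros((self.n_genes, self.n_genes), dtype=np.float64)
        if self.edges:
            rows, cols = zip(*self.edges)
            a[list(rows), list(cols)] = 1.0
        return a

    def degrees(self) -> np.ndarray:
        """Total degree (in + out) per node."""
        deg = np.zeros(self.n_genes, dtype=np.int64)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def edge_names(self) -> set[tuple[str, str]]:
        return {(self.gene_ids[i], self.gene_ids[j]) for i, j in self.edges}

    def with_edges(self, edges: set[tuple[int, int]]) -> "PriorNetwork":
        """Copy with a new edge set and the hub partition cleared."""
        return PriorNetwork(list(self.gene_ids), set(edges))


@dataclass
class GroundTruthNetwork:
    """Reference TF -> target edges used only for evaluation."""

    edges: set[tuple[str, str]]
    tf_set: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.edges = {(str(a), str(b)) for a, b in self.edges}
        if not self.tf_set:
            self.tf_set = {a for a, _ in self.edges}
        bad = {a for a, _ in self.edges if a not in self.tf_set}
        if bad:
            raise ValueError(f"truth edges with non-TF sources: {sorted(bad)}")

    def restricted(self, genes: list[str] | set[str]) -> "GroundTruthNetwork":
        universe = set(genes)
        edges = {
            (a, b)
            for a, b in self.edges
            if a in universe and b in universe and a != b
        }
        return GroundTruthNetwork(edges, self.tf_set & universe)


def _duplicates(items: list[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def load_expression(
    path,
    format: str = "dense-tsv",
    genes_file=None,
    cells_file=None,
) -> GeneExpressionMatrix:
    """Read a raw genes x cells expression matrix.

    ``dense-tsv`` expects a header row of cell ids and the gene id in the
    first column.  ``matrix-market`` expects a ``.mtx`` triplet file plus
    one-name-per-line ``genes_file`` and ``cells_file``.
    """
    if format == "dense-tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        for col in df.columns[df.dtypes.eq(object)]:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = bad.idxmax()
                raise ValueError(
                    f"non-numeric expression entry at gene {row!r}, cell {col!r}"
                )
            df[col] = coerced
        values = df.to_numpy(dtype=np.float64)
        gene_ids = [str(g) for g in df.index]
        cell_ids = [str(c) for c in df.columns]
    elif format == "matrix-market":
        if genes_file is None or cells_file is None:
            raise ValueError(
                "matrix-market input requires genes_file and cells_file"
            )
        mat = scipy.io.mmread(path)
        values = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat,
            dtype=np.float64,
        )
        gene_ids = _read_names(genes_file)
        cell_ids = _read_names(cells_file)
    else:
        raise ValueError(f"unknown expression format: {format!r}")

    return GeneExpressionMatrix(values, gene_ids, cell_ids, normalized=False)


def _read_names(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def load_tf_list(path) -> list[str]:
    """Read a TF list, one gene name per line."""
    return _read_names(path)


def load_edge_list(path) -> list[tuple[str, str]]:
    """Read a regulator/target edge list TSV; a third weight column is
    accepted and ignored."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"edge list {path} needs at least 2 columns")
    first = (str(df.iloc[0, 0]).lower(), str(df.iloc[0, 1]).lower())
    if first in {("regulator", "target"), ("tf", "target"), ("source", "target")}:
        df = df.iloc[1:]
    return [(str(a), str(b)) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])]


def load_ground_truth(path, tf_set=None) -> GroundTruthNetwork:
    edges = set(load_edge_list(path))
    return GroundTruthNetwork(edges, set(tf_set) if tf_set else set())


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def normalize_expression(
    raw: GeneExpressionMatrix, scale: float = 1e4
) -> GeneExpressionMatrix:
    """Per-gene total-count normalization followed by log1p.

    Each gene row is divided by its row total (all-zero rows stay zero),
    multiplied by ``scale``, then mapped through log(1 + x).
    """
    if raw.normalized:
        raise ValueError("expression matrix is already normalized")
    if np.any(raw.values < 0):
        raise ValueError("raw expression matrix contains negative entries")
    if scale <= 0:
        raise ValueError("scale must be positive")
    totals = raw.values.sum(axis=1, keepdims=True)
    safe = np.where(totals > 0, totals, 1.0)
    values = np.log1p(raw.values / safe * scale)
    return GeneExpressionMatrix(
        values, list(raw.gene_ids), list(raw.cell_ids), normalized=True
    )


def select_genes(
    expr: GeneExpressionMatrix, tf_list, n_top: int
) -> GeneExpressionMatrix:
    """Keep variable TFs plus the ``n_top`` most variable genes.

    All TFs present in the matrix with nonzero variance are retained,
    unioned with the ``n_top`` highest-variance genes overall; the original
    gene order is preserved.  TFs absent from the matrix are skipped with a
    log message.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    if n_top > expr.n_genes:
        warnings.warn(
            f"n_top={n_top} exceeds gene count {expr.n_genes}; keeping all genes"
        )
        n_top = expr.n_genes
    variances = expr.values.var(axis=1)
    index = expr.gene_index()
    missing = [tf for tf in tf_list if tf not in index]
    if missing:
        logger.info("TFs absent from expression matrix skipped: %s", missing)
    keep = {
        index[tf]
        for tf in tf_list
        if tf in index and variances[index[tf]] > 0
    }
    # highest-variance genes; stable order among exact ties
    order = np.argsort(-variances, kind="stable")
    keep.update(order[:n_top].tolist())
    rows = sorted(keep)
    return GeneExpressionMatrix(
        expr.values[rows],
        [expr.gene_ids[i] for i in rows],
        list(expr.cell_ids),
        normalized=expr.normalized,
    )


def build_prior_graph(
    edge_list, expr: GeneExpressionMatrix
) -> PriorNetwork:
    """Restrict a named edge list to the expression genes.

    Self-loops are dropped and duplicate directed edges collapsed; every
    expressed gene becomes a node, so genes absent from the prior are
    isolated nodes.
    """
    if not edge_list:
        raise ValueError("prior edge list is empty")
    index = expr.gene_index()
    edges = {
        (index[a], index[b])
        for a, b in edge_list
        if a in index and b in index and a != b
    }
    if not edges:
        raise ValueError("prior and expression share no genes")
    return PriorNetwork(list(expr.gene_ids), edges)


def identify_hubs(
    prior: PriorNetwork, hub_fraction: float = 0.15
) -> PriorNetwork:
    """Partition the prior into high-centrality and remaining subgraphs.

    The floor(hub_fraction * N) nodes of highest total degree (in + out)
    form Vs, ties broken by lexicographic gene id; Es is the set of edges
    with *both* endpoints in Vs, and every other edge belongs to Er.
    """
    if not 0 < hub_fraction < 1:
        raise ValueError("hub_fraction must be in (0, 1)")
    n_hubs = int(np.floor(hub_fraction * prior.n_genes))
    deg = prior.degrees()
    ranked = sorted(range(prior.n_genes), key=lambda i: (-deg[i], prior.gene_ids[i]))
    hub_nodes = set(ranked[:n_hubs])
    hub_edges = {(i, j) for i, j in prior.edges if i in hub_nodes and j in hub_nodes}
    return replace(prior, hub_nodes=hub_nodes, hub_edges=hub_edges)
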