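"""Embedding-space analytics downstream of network inference.

Covers gene clustering on the dual embeddings (k-means or Leiden on a kNN
graph), target-set similarity between regulators with Jaccard-family
metrics, cumulative co-clustering curves for the most similar pairs,
differential out-degree ranking of TFs between two sample groups, and the
motif hit-ratio statistic computed from a precomputed motif-hit table.

The motif scan itself (e.g. FIMO at p < 1e-4 over +/-200 kb TSS windows
with JASPAR motifs) is upstream of this package; only its (TF, gene, hit)
output table is consumed here.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ranksums
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors

from .inference import InferredGRN, RegulatoryScoreMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterAssignment",
    "DifferentialTFRanking",
    "HitRatioTable",
    "cluster_embeddings",
    "target_jaccard",
    "set_similarity",
    "co_cluster_curve",
    "ranked_tf_pairs",
    "differential_out_degree",
    "tf_hit_ratio",
]


@dataclass
class ClusterAssignment:
    labels: dict[str, int]
    method: str
    parameter: float
    embedding_role: str = "out"

    def same_cluster(self, a: str, b: str) -> bool:
        return self.labels[a] == self.labels[b]


@dataclass
class DifferentialTFRanking:
    """Per-TF up/down counts of significantly changed edges, ranked."""

    table: pd.DataFrame  # columns: tf, n_up, n_down, differential_out_degree
    edge_pvalues: pd.DataFrame  # columns: tf, target, pvalue, direction


@dataclass
class HitRatioTable:
    per_gene: pd.DataFrame  # columns: gene, n_predicted, n_hits, hit_ratio
    nonzero_proportion: float


def _standardize(emb: np.ndarray) -> np.ndarray:
    mu = emb.mean(axis=0)
    sd = emb.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (emb - mu) / sd


def cluster_embeddings(
    emb: np.ndarray,
    gene_ids,
    method: str = "kmeans",
    param: float = 6,
    seed: int = 0,
    knn: int = 15,
    role: str = "out",
) -> ClusterAssignment:
    """Cluster standardized embeddings with k-means or Leiden.

    ``param`` is the cluster count for k-means or the resolution for
    Leiden; Leiden runs on a k-nearest-neighbor graph of the standardized
    embeddings.
    """
    emb = np.asarray(emb, dtype=np.float64)
    gene_ids = list(gene_ids)
    z = _standardize(emb)
    n = z.shape[0]
    if method == "kmeans":
        k = int(param)
        if k >= n + 1 or k < 1:
            raise ValueError(f"k={k} invalid for {n} genes")
        km = KMeans(n_clusters=k, random_state=seed, n_init=10)
        raw = km.fit_predict(z)
    elif method == "leiden":
        import igraph
        import leidenalg

        k = min(knn, n - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(z)
        _, idx = nn.kneighbors(z)
        edges = {tuple(sorted((i, int(j)))) for i in range(n) for j in idx[i, 1:]}
        g = igraph.Graph(n=n, edges=sorted(edges), directed=False)
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=float(param),
            seed=seed,
        )
        raw = np.asarray(part.membership)
    else:
        raise ValueError(f"unknown clustering method: {method!r}")
    # relabel to contiguous integers by first appearance
    remap: dict[int, int] = {}
    labels = {}
    for gid, lab in zip(gene_ids, raw):
        labels[gid] = remap.setdefault(int(lab), len(remap))
    return ClusterAssignment(labels, method, float(param), role)


def set_similarity(a: set, b: set, metric: str = "jaccard") -> float:
    """Similarity between two target sets; empty sets give 0."""
    if not a or not b:
        return 0.0
    inter = len(a & b)
    if metric == "jaccard":
        return inter / len(a | b)
    if metric == "dice":
        return 2 * inter / (len(a) + len(b))
    if metric == "cosine":
        return inter / np.sqrt(len(a) * len(b))
    if metric == "kulczynski":
        return 0.5 * (inter / len(a) + inter / len(b))
    raise ValueError(f"unknown similarity metric: {metric!r}")


def target_jaccard(grn: InferredGRN, a: str, b: str, metric: str = "jaccard") -> float:
    """Similarity of two TFs' predicted target sets (0 if either is absent)."""
    sets = grn.target_sets()
    return set_similarity(sets.get(a, set()), sets.get(b, set()), metric)


def ranked_tf_pairs(
    grn: InferredGRN, metric: str = "jaccard"
) -> list[tuple[str, str, float]]:
    """All TF pairs sorted by target-set similarity desc, ties lexicographic."""
    sets = grn.target_sets()
    tfs = sorted(sets)
    pairs = [
        (a, b, set_similarity(sets[a], sets[b], metric))
        for a, b in itertools.combinations(tfs, 2)
    ]
    return sorted(pairs, key=lambda t: (-t[2], t[0], t[1]))


def co_cluster_curve(
    pairs: list[tuple[str, str, float]] | list[tuple[str, str]],
    labels: ClusterAssignment,
    top_n: int = 500,
) -> np.ndarray:
    """Cumulative proportion of top-r pairs sharing a cluster, r = 1..top_n."""
    if len(pairs) < top_n:
        warnings.warn(
            f"only {len(pairs)} pairs available; truncating curve from {top_n}"
        )
        top_n = len(pairs)
    hits = np.array(
        [labels.same_cluster(p[0], p[1]) for p in pairs[:top_n]], dtype=np.float64
    )
    return np.cumsum(hits) / np.arange(1, top_n + 1)


def differential_out_degree(
    matrices: list[RegulatoryScoreMatrix],
    groups: list[str],
    tf_set,
    edge_universe: list[tuple[str, str]] | None = None,
    edges_per_gene: int = 10,
    alpha: float = 0.05,
    adjust: str | None = None,
) -> DifferentialTFRanking:
    """Rank TFs by net count of significantly changed edges between groups.

    Each edge's score across group-A samples is compared with group-B
    samples by a two-sided Wilcoxon rank-sum test; an edge counts as up
    (down) for its TF when p < alpha and the group-A median is higher
    (lower).  ``adjust='bh'`` applies Benjamini-Hochberg before
    thresholding.  The default edge universe is the union of every
    sample's top H = edges_per_gene * N edges.
    """
    if len(matrices) != len(groups):
        raise ValueError("one group label per score matrix is required")
    names = sorted(set(groups))
    if len(names) != 2:
        raise ValueError(f"exactly two groups required, got {names}")
    ga, gb = names
    idx_a = [i for i, g in enumerate(groups) if g == ga]
    idx_b = [i for i, g in enumerate(groups) if g == gb]
    if len(idx_a) < 3 or len(idx_b) < 3:
        raise ValueError("each group needs at least 3 samples")
    gene_ids = matrices[0].gene_ids
    index = {g: i for i, g in enumerate(gene_ids)}
    for m in matrices:
        if m.gene_ids != gene_ids:
            raise ValueError("score matrices must share one gene universe")
    tfs = sorted(set(tf_set) & set(gene_ids))

    if edge_universe is None:
        h = edges_per_gene * len(gene_ids)
        universe: set[tuple[str, str]] = set()
        for m in matrices:
            flat = [
                (tf, tgt, m.matrix[index[tf], index[tgt]])
                for tf in tfs
                for tgt in gene_ids
                if tf != tgt
            ]
            flat.sort(key=lambda t: (-t[2], t[0], t[1]))
            universe.update((a, b) for a, b, _ in flat[: min(h, len(flat))])
        edge_universe = sorted(universe)

    records = []
    for tf, tgt in edge_universe:
        i, j = index[tf], index[tgt]
        xs = np.array([matrices[s].matrix[i, j] for s in idx_a])
        ys = np.array([matrices[s].matrix[i, j] for s in idx_b])
        stat = ranksums(xs, ys)
        direction = np.sign(np.median(xs) - np.median(ys))
        records.append((tf, tgt, float(stat.pvalue), int(direction)))
    edge_df = pd.DataFrame(records, columns=["tf", "target", "pvalue", "direction"])

    pvals = edge_df["pvalue"].to_numpy()
    if adjust == "bh":
        m = len(pvals)
        order = np.argsort(pvals)
        adj = np.empty(m)
        running = 1.0
        for rank_pos in range(m - 1, -1, -1):
            i = order[rank_pos]
            running = min(running, pvals[i] * m / (rank_pos + 1))
            adj[i] = running
        pvals = adj
    elif adjust is not None:
        raise ValueError(f"unknown adjustment: {adjust!r}")
    sig = pvals < alpha

    rows = []
    for tf in tfs:
        mask = (edge_df["tf"] == tf).to_numpy()
        n_up = int(np.sum(sig & mask & (edge_df["direction"] == 1)))
        n_down = int(np.sum(sig & mask & (edge_df["direction"] == -1)))
        rows.append((tf, n_up, n_down, n_up - n_down))
    table = pd.DataFrame(
        rows, columns=["tf", "n_up", "n_down", "differential_out_degree"]
    ).sort_values(
        ["differential_out_degree", "tf"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return DifferentialTFRanking(table, edge_df)


def tf_hit_ratio(
    grn: InferredGRN,
    hit_table: pd.DataFrame,
    top_fraction: float = 0.05,
) -> HitRatioTable:
    """Per-target fraction of predicted TFs with a motif hit.

    Restricts to the top ``top_fraction`` of GRN edges by score, groups by
    target gene, and computes hits / predicted per gene; (TF, gene) pairs
    missing from the table count as no hit.  Also reports the proportion
    of target genes with a non-zero hit ratio.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    n_top = int(np.floor(top_fraction * len(grn.edges)))
    if n_top == 0:
        raise ValueError(
            f"top_fraction={top_fraction} selects no edges from a "
            f"{len(grn.edges)}-edge network"
        )
    top = grn.edges.sort_values(
        ["score", "tf", "target"], ascending=[False, True, True], kind="mergesort"
    ).head(n_top)
    hits = {
        (str(a), str(b)): int(h)
        for a, b, h in zip(hit_table["tf"], hit_table["gene"], hit_table["hit"])
    }
    missing = [
        (a, b) for a, b in zip(top["tf"], top["target"]) if (a, b) not in hits
    ]
    if missing:
        logger.info("%d (TF, gene) pairs missing from hit table; counted as 0", len(missing))
    rows = []
    for gene, sub in top.groupby("target"):
        n_pred = len(sub)
        n_hit = sum(hits.get((tf, gene), 0) for tf in sub["tf"])
        rows.append((gene, n_pred, n_hit, n_hit / n_pred))
    per_gene = pd.DataFrame(
        rows, columns=["gene", "n_predicted", "n_hits", "hit_ratio"]
    ).sort_values("gene", kind="mergesort").reset_index(drop=True)
    nonzero = float((per_gene["hit_ratio"] > 0).mean())
    return HitRatioTable(per_gene, nonzero)
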