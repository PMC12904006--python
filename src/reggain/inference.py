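"""From trained encoders to a ranked, directed TF -> target network.

After training, one clean forward pass (un-corrupted features and prior
adjacency, no projection head) yields final out/in embeddings.  These are
L2-normalized row-wise and combined into the regulatory score matrix

    M = P o (h_out_hat  h_in_hat^T)

where P multiplies prior-edge entries by gamma (>= 1) and leaves the rest
at 1, so a prior edge with the same cosine outranks a non-prior pair.
Training plus scoring is repeated over several seeds and the score
matrices averaged; the top H = edges_per_gene * N scoring TF -> target
pairs (self-loops excluded) form the inferred network.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .augment import AugmentationConfig
from .data import GeneExpressionMatrix, PriorNetwork
from .encoder import DualEmbeddings, EncoderConfig, dual_encode
from .training import LossConfig, TrainingResult, train

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreConfig",
    "RegulatoryScoreMatrix",
    "InferredGRN",
    "clean_embeddings",
    "score_matrix",
    "average_runs",
    "select_edges",
    "infer_grn",
    "write_grn",
    "read_grn",
]


@dataclass(frozen=True)
class ScoreConfig:
    """Scoring and edge-selection settings."""

    gamma: float = 10.0       # prior-edge weight in P; 1 disables the prior
    n_runs: int = 10          # training repetitions averaged
    edges_per_gene: int = 10  # H = edges_per_gene * n_genes

    def __post_init__(self) -> None:
        if self.gamma < 1:
            raise ValueError("gamma must be >= 1")
        if self.n_runs < 1 or self.edges_per_gene < 1:
            raise ValueError("n_runs and edges_per_gene must be >= 1")


@dataclass
class RegulatoryScoreMatrix:
    """N x N regulator -> target score matrix (diagonal excluded from ranking)."""

    matrix: np.ndarray
    gene_ids: list[str]
    n_runs_averaged: int = 1


@dataclass
class InferredGRN:
    """Ranked directed TF -> target edge list."""

    edges: pd.DataFrame  # columns: tf, target, score, rank
    tf_set: set[str] = field(default_factory=set)
    seed: int | None = None

    def target_sets(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for tf, tgt in zip(self.edges["tf"], self.edges["target"]):
            out.setdefault(tf, set()).add(tgt)
        return out

    def edge_set(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["tf"], self.edges["target"]))


def clean_embeddings(
    result: TrainingResult,
    X: GeneExpressionMatrix,
    prior: PriorNetwork,
) -> DualEmbeddings:
    """Forward pass on the un-corrupted graph; no projection head."""
    h_out, h_in = dual_encode(
        X.values,
        prior.adjacency(),
        result.params_out,
        result.params_in,
        result.encoder_config,
    )
    return DualEmbeddings(h_out.data, h_in.data, "clean")


def _row_unit(h: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(h, axis=1, keepdims=True)
    return h / np.where(norms > 0, norms, 1.0)


def score_matrix(
    emb: DualEmbeddings, prior: PriorNetwork, gamma: float = 10.0
) -> RegulatoryScoreMatrix:
    """M = P o (h_out_hat h_in_hat^T) with the diagonal zeroed out."""
    m = _row_unit(emb.h_out) @ _row_unit(emb.h_in).T
    if gamma != 1.0:
        p = np.ones_like(m)
        if prior.edges:
            rows, cols = zip(*prior.edges)
            p[list(rows), list(cols)] = gamma
        m = m * p
    np.fill_diagonal(m, 0.0)
    return RegulatoryScoreMatrix(m, list(prior.gene_ids))


def average_runs(
    X: GeneExpressionMatrix,
    prior: PriorNetwork,
    base_seed: int,
    score_cfg: ScoreConfig | None = None,
    encoder_cfg: EncoderConfig | None = None,
    loss_cfg: LossConfig | None = None,
    aug_cfg: AugmentationConfig | None = None,
) -> RegulatoryScoreMatrix:
    """Element-wise mean of score matrices over n_runs trainings.

    Run r uses seed ``base_seed + r`` for both weight initialization and
    augmentation draws.
    """
    score_cfg = score_cfg or ScoreConfig()
    acc: np.ndarray | None = None
    for r in range(score_cfg.n_runs):
        try:
            result = train(
                X, prior, base_seed + r, encoder_cfg, loss_cfg, aug_cfg
            )
        except Exception as exc:
            raise RuntimeError(f"inference run {r} failed: {exc}") from exc
        emb = clean_embeddings(result, X, prior)
        m = score_matrix(emb, prior, score_cfg.gamma).matrix
        acc = m if acc is None else acc + m
    return RegulatoryScoreMatrix(
        acc / score_cfg.n_runs, list(prior.gene_ids), score_cfg.n_runs
    )


def select_edges(
    scores: RegulatoryScoreMatrix,
    tf_set,
    cfg: ScoreConfig | None = None,
    seed: int | None = None,
) -> InferredGRN:
    """Top H = edges_per_gene * N TF -> target edges by averaged score.

    Ties break deterministically by (score desc, tf id, target id).
    """
    cfg = cfg or ScoreConfig()
    gene_ids = scores.gene_ids
    index = {g: i for i, g in enumerate(gene_ids)}
    tfs = sorted(set(tf_set) & set(gene_ids))
    if not tfs:
        raise ValueError("no TFs found in the scored gene universe")
    n = len(gene_ids)
    h = cfg.edges_per_gene * n
    records = []
    for tf in tfs:
        i = index[tf]
        for j, target in enumerate(gene_ids):
            if i == j:
                continue
            records.append((tf, target, scores.matrix[i, j]))
    df = pd.DataFrame(records, columns=["tf", "target", "score"])
    if h > len(df):
        warnings.warn(
            f"requested {h} edges but only {len(df)} TF-target candidates exist"
        )
        h = len(df)
    df = df.sort_values(
        ["score", "tf", "target"], ascending=[False, True, True], kind="mergesort"
    ).head(h)
    df["rank"] = np.arange(1, len(df) + 1)
    return InferredGRN(df.reset_index(drop=True), set(tfs), seed)


def infer_grn(
    X: GeneExpressionMatrix,
    prior: PriorNetwork,
    tf_set,
    base_seed: int,
    score_cfg: ScoreConfig | None = None,
    encoder_cfg: EncoderConfig | None = None,
    loss_cfg: LossConfig | None = None,
    aug_cfg: AugmentationConfig | None = None,
) -> InferredGRN:
    """Full pipeline: multi-run training, score averaging, top-H selection."""
    score_cfg = score_cfg or ScoreConfig()
    avg = average_runs(
        X, prior, base_seed, score_cfg, encoder_cfg, loss_cfg, aug_cfg
    )
    grn = select_edges(avg, tf_set, score_cfg, base_seed)
    return grn


def write_grn(grn: InferredGRN, path) -> None:
    """Write a 4-column TSV: tf, target, score (full precision), rank."""
    df = grn.edges.copy()
    df["score"] = df["score"].map(repr)
    df.to_csv(path, sep="\t", index=False)


def read_grn(path) -> InferredGRN:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"tf": str, "target": str, "score": np.float64, "rank": np.int64},
        float_precision="round_trip",
    )
    return InferredGRN(df, set(df["tf"]))
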