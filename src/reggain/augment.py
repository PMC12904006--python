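"""Stochastic graph-view generation for contrastive learning.

Two views of the prior graph are produced each epoch:

* **View 1** corrupts uniformly — every edge is dropped with probability
  ``alpha1`` and every node's feature row is zeroed with probability
  ``beta1``.
* **View 2** is topology-aware — edges inside the hub subgraph (Es) are
  dropped with the higher rate ``alpha2`` while remaining edges (Er) use
  ``alpha3``; hub-node feature rows are masked with ``beta2`` and the rest
  with ``beta3``.  Because scale-free networks shrug off uniform noise,
  hitting the hubs harder produces genuinely distinct views.

Masking is row-level: a selected node's whole feature vector is zeroed, so
each row of a view is either identical to the input row or exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import GeneExpressionMatrix, PriorNetwork

__all__ = ["AugmentationConfig", "GraphView", "random_view", "topology_aware_view", "view_seed"]


@dataclass(frozen=True)
class AugmentationConfig:
    """Corruption rates for the two graph views."""

    alpha1: float = 0.3   # View 1 edge-drop rate
    alpha2: float = 0.6   # View 2 drop rate for hub-subgraph edges (Es)
    alpha3: float = 0.3   # View 2 drop rate for remaining edges (Er)
    beta1: float = 0.2    # View 1 feature-mask rate
    beta2: float = 0.5    # View 2 mask rate for hub nodes (Vs)
    beta3: float = 0.2    # View 2 mask rate for other nodes (Vr)

    def __post_init__(self) -> None:
        for name in ("alpha1", "alpha2", "alpha3", "beta1", "beta2", "beta3"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name}={v} must be in [0, 1)")


@dataclass
class GraphView:
    """One corrupted (features, adjacency) pair."""

    features: np.ndarray       # N x d, masked rows exactly zero
    adjacency: np.ndarray      # N x N binary, subset of the prior edges
    view_id: int               # 1 or 2
    seed: int


def view_seed(base_seed: int, epoch: int, view_id: int) -> int:
    """Per-epoch, per-view seed so every augmentation draw is replayable."""
    return base_seed * 1_000_000 + epoch * 4 + view_id


def _apply(
    prior: PriorNetwork,
    X: GeneExpressionMatrix,
    edge_drop_prob: np.ndarray,
    node_mask_prob: np.ndarray,
    view_id: int,
    seed: int,
) -> GraphView:
    rng = np.random.default_rng(seed)
    n = prior.n_genes
    edges = sorted(prior.edges)
    keep = rng.random(len(edges)) >= edge_drop_prob
    adj = np.zeros((n, n), dtype=np.float64)
    for (i, j), k in zip(edges, keep):
        if k:
            adj[i, j] = 1.0
    masked = rng.random(n) < node_mask_prob
    feats = X.values.copy()
    feats[masked] = 0.0
    return GraphView(feats, adj, view_id, seed)


def random_view(
    prior: PriorNetwork,
    X: GeneExpressionMatrix,
    cfg: AugmentationConfig,
    seed: int,
) -> GraphView:
    """View 1: uniform edge dropping and feature masking."""
    n_edges = prior.n_edges
    return _apply(
        prior,
        X,
        np.full(n_edges, cfg.alpha1),
        np.full(prior.n_genes, cfg.beta1),
        view_id=1,
        seed=seed,
    )


def topology_aware_view(
    prior: PriorNetwork,
    X: GeneExpressionMatrix,
    cfg: AugmentationConfig,
    seed: int,
) -> GraphView:
    """View 2: hub-aware edge dropping and feature masking."""
    if prior.hub_nodes is None or prior.hub_edges is None:
        raise ValueError(
            "prior network has no hub partition; run identify_hubs first"
        )
    edges = sorted(prior.edges)
    edge_p = np.array(
        [cfg.alpha2 if e in prior.hub_edges else cfg.alpha3 for e in edges]
    )
    node_p = np.array(
        [
            cfg.beta2 if i in prior.hub_nodes else cfg.beta3
            for i in range(prior.n_genes)
        ]
    )
    return _apply(prior, X, edge_p, node_p, view_id=2, seed=seed)
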