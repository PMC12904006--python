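"""Contrastive objective and training loop.

For each gene the embedding under one view is the anchor and the same
gene's embedding under the other view is the positive; every other gene's
embedding from either view — within the same role — is a negative.  With
S(u, v) = exp(cos(g(u), g(v)) / tau) and g the projection head, the anchor
loss for gene i in view 1 (out role) is

    -log  S(h_i^(1), h_i^(2)) /
          [ S(h_i^(1), h_i^(2)) + sum_{k != i} ( S(h_i^(1), h_k^(1))
                                               + S(h_i^(1), h_k^(2)) ) ]

The out- and in-role losses are summed per gene, the two view directions
symmetrized, and the total averaged over 2N anchor terms.

With a single gene there are no negatives and the loss is exactly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Adam, Tensor
from .augment import AugmentationConfig, random_view, topology_aware_view, view_seed
from .data import GeneExpressionMatrix, PriorNetwork
from .encoder import (
    EncoderConfig,
    EncoderParams,
    ProjectionParams,
    dual_encode,
    init_encoder_params,
    init_projection_params,
    project,
)

logger = logging.getLogger(__name__)

__all__ = ["LossConfig", "TrainingResult", "pair_similarity", "contrastive_loss", "train"]


@dataclass(frozen=True)
class LossConfig:
    """Contrastive-loss and optimizer settings."""

    temperature: float = 3.0
    epochs: int = 500
    learning_rate: float = 1e-3

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class TrainingResult:
    params_out: EncoderParams
    params_in: EncoderParams
    proj_out: ProjectionParams
    proj_in: ProjectionParams
    loss_trace: list[float]
    seed: int
    encoder_config: EncoderConfig = field(default_factory=EncoderConfig)


def pair_similarity(u: np.ndarray, v: np.ndarray, tau: float) -> float:
    """S(u, v) = exp(cos(u, v) / tau); the cosine with a zero vector is 0."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    cos = 0.0 if nu == 0 or nv == 0 else float(u @ v) / (nu * nv)
    return float(np.exp(cos / tau))


def _row_normalize(z: Tensor, eps: float = 1e-12) -> Tensor:
    sq = (z * z).sum(axis=1, keepdims=True)
    return z / (sq + eps).sqrt()


def _role_loss(z1: Tensor, z2: Tensor, tau: float, eye: np.ndarray) -> Tensor:
    """Sum over genes of both view-direction anchor losses for one role."""
    z1n = _row_normalize(z1)
    z2n = _row_normalize(z2)
    s11 = ((z1n @ z1n.T) * (1.0 / tau)).exp()
    s22 = ((z2n @ z2n.T) * (1.0 / tau)).exp()
    s12 = ((z1n @ z2n.T) * (1.0 / tau)).exp()
    pos = (s12 * eye).sum(axis=1)                     # S(h_i^1, h_i^2)
    diag11 = (s11 * eye).sum(axis=1)
    diag22 = (s22 * eye).sum(axis=1)
    den1 = s11.sum(axis=1) - diag11 + s12.sum(axis=1)
    den2 = s22.sum(axis=1) - diag22 + s12.T.sum(axis=1)
    return -((pos / den1).log().sum() + (pos / den2).log().sum())


def contrastive_loss(
    h1_out,
    h2_out,
    h1_in,
    h2_in,
    proj_out: ProjectionParams,
    proj_in: ProjectionParams,
    tau: float = 3.0,
) -> Tensor:
    """Symmetrized dual-role InfoNCE loss, averaged over 2N anchor pairs."""
    h1_out = Tensor.as_tensor(h1_out)
    n = h1_out.shape[0]
    eye = np.eye(n)
    z1o = project(h1_out, proj_out)
    z2o = project(Tensor.as_tensor(h2_out), proj_out)
    z1i = project(Tensor.as_tensor(h1_in), proj_in)
    z2i = project(Tensor.as_tensor(h2_in), proj_in)
    total = _role_loss(z1o, z2o, tau, eye) + _role_loss(z1i, z2i, tau, eye)
    return total * (1.0 / (2 * n))


def train(
    X: GeneExpressionMatrix,
    prior: PriorNetwork,
    seed: int,
    encoder_cfg: EncoderConfig | None = None,
    loss_cfg: LossConfig | None = None,
    aug_cfg: AugmentationConfig | None = None,
) -> TrainingResult:
    """Train the dual encoders with fresh graph views every epoch.

    Fully reproducible: weight initialization draws from ``seed`` and each
    epoch's two views use :func:`~reggain.augment.view_seed`.
    """
    encoder_cfg = encoder_cfg or EncoderConfig()
    loss_cfg = loss_cfg or LossConfig()
    aug_cfg = aug_cfg or AugmentationConfig()
    if not X.normalized:
        raise ValueError("expression matrix must be normalized before training")
    if prior.hub_nodes is None:
        raise ValueError("prior network needs a hub partition; run identify_hubs")

    rng = np.random.default_rng(seed)
    params_out = init_encoder_params(encoder_cfg, X.n_cells, rng)
    params_in = init_encoder_params(encoder_cfg, X.n_cells, rng)
    proj_out = init_projection_params(encoder_cfg, rng)
    proj_in = init_projection_params(encoder_cfg, rng)
    trainable = (
        params_out.all_tensors()
        + params_in.all_tensors()
        + proj_out.all_tensors()
        + proj_in.all_tensors()
    )
    optimizer = Adam(trainable, lr=loss_cfg.learning_rate)

    loss_trace: list[float] = []
    for epoch in range(loss_cfg.epochs):
        v1 = random_view(prior, X, aug_cfg, view_seed(seed, epoch, 1))
        v2 = topology_aware_view(prior, X, aug_cfg, view_seed(seed, epoch, 2))
        h1o, h1i = dual_encode(
            v1.features, v1.adjacency, params_out, params_in, encoder_cfg, 1
        )
        h2o, h2i = dual_encode(
            v2.features, v2.adjacency, params_out, params_in, encoder_cfg, 2
        )
        loss = contrastive_loss(
            h1o, h2o, h1i, h2i, proj_out, proj_in, loss_cfg.temperature
        )
        value = loss.item()
        if not np.isfinite(value):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        optimizer.zero_grad()
        loss.backward()
        optimizer.step()
        loss_trace.append(value)
        logger.info("epoch %d loss %.6f", epoch, value)

    return TrainingResult(
        params_out, params_in, proj_out, proj_in, loss_trace, seed, encoder_cfg
    )
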