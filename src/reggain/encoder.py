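"""Dual-role high-order graph convolutional encoders.

Each gene gets two embeddings: an *out*-embedding describing its behavior
as a regulator, computed on the prior adjacency A, and an *in*-embedding
describing its behavior as a target, computed on the transposed adjacency
A^T (normalized after transposition).  The two encoders share architecture
but not weights.

A single layer aggregates several neighborhood orders at once:

    h^(l) = ||_{j in S} tanh( A_hat^j  h^(l-1)  W_j^(l) )

where A_hat = D^{-1/2} (A + I) D^{-1/2} with D the diagonal of row sums of
A + I, A_hat^0 = I, and || is column-wise concatenation.  With the default
orders S = {0, 1, 2} and per-order widths [[80, 80, 10], [40, 40, 5],
[16, 16, 2]] the three layers produce widths 170, 85 and 34, so the final
embedding has 34 dimensions (16 + 16 + 2).

Layers are bias-free; the zero feature matrix therefore propagates to a
zero embedding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor, concat

__all__ = [
    "EncoderConfig",
    "NormalizedAdjacency",
    "EncoderParams",
    "ProjectionParams",
    "DualEmbeddings",
    "normalize_adjacency",
    "adjacency_powers",
    "high_order_conv",
    "encode",
    "dual_encode",
    "init_encoder_params",
    "init_projection_params",
    "project",
]

DEFAULT_ORDERS = (0, 1, 2)
DEFAULT_LAYER_DIMS = ((80, 80, 10), (40, 40, 5), (16, 16, 2))


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture of one high-order GCN encoder."""

    orders: tuple[int, ...] = DEFAULT_ORDERS
    layer_dims: tuple[tuple[int, ...], ...] = DEFAULT_LAYER_DIMS
    projection_hidden: int = 64

    def __post_init__(self) -> None:
        if 0 not in self.orders:
            raise ValueError("orders must include 0 (the node's own features)")
        if sorted(self.orders) != list(self.orders):
            raise ValueError("orders must be strictly increasing")
        for l, dims in enumerate(self.layer_dims):
            if len(dims) != len(self.orders):
                raise ValueError(
                    f"layer {l} has {len(dims)} widths for {len(self.orders)} orders"
                )
            if any(w < 1 for w in dims):
                raise ValueError(f"layer {l} has a non-positive width")

    @property
    def embedding_dim(self) -> int:
        return sum(self.layer_dims[-1])


@dataclass
class NormalizedAdjacency:
    """Symmetrically normalized adjacency with self-loops."""

    matrix: np.ndarray
    view_id: int | str = "clean"


@dataclass
class EncoderParams:
    """Per-layer, per-order weight matrices of one encoder."""

    weights: list[list[Tensor]]

    def all_tensors(self) -> list[Tensor]:
        return [w for layer in self.weights for w in layer]


@dataclass
class ProjectionParams:
    """Two-layer projection head used only inside the contrastive loss."""

    w1: Tensor
    w2: Tensor

    def all_tensors(self) -> list[Tensor]:
        return [self.w1, self.w2]


@dataclass
class DualEmbeddings:
    """Out- (regulator-role) and in- (target-role) embeddings per gene."""

    h_out: np.ndarray
    h_in: np.ndarray
    view_id: int | str = "clean"


def normalize_adjacency(adj: np.ndarray, view_id: int | str = "clean") -> NormalizedAdjacency:
    """A_hat = D^{-1/2} (A + I) D^{-1/2}, D = diag of row sums of A + I."""
    adj = np.asarray(adj, dtype=np.float64)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    a = adj + np.eye(adj.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(a.sum(axis=1))
    return NormalizedAdjacency(
        d_inv_sqrt[:, None] * a * d_inv_sqrt[None, :], view_id
    )


def adjacency_powers(
    norm: NormalizedAdjacency, orders: tuple[int, ...]
) -> dict[int, np.ndarray]:
    """Matrix powers A_hat^j for every order j (j = 0 gives the identity).

    Powers are computed once per view and reused by every layer.
    """
    n = norm.matrix.shape[0]
    powers: dict[int, np.ndarray] = {}
    current = np.eye(n)
    for j in range(max(orders) + 1):
        if j > 0:
            current = current @ norm.matrix
        if j in orders:
            powers[j] = current.copy()
    return powers


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_encoder_params(
    cfg: EncoderConfig, in_dim: int, rng: np.random.Generator
) -> EncoderParams:
    weights: list[list[Tensor]] = []
    dim = in_dim
    for dims in cfg.layer_dims:
        layer = [
            Tensor(glorot(rng, dim, w), requires_grad=True) for w in dims
        ]
        weights.append(layer)
        dim = sum(dims)
    return EncoderParams(weights)


def init_projection_params(
    cfg: EncoderConfig, rng: np.random.Generator
) -> ProjectionParams:
    e = cfg.embedding_dim
    h = cfg.projection_hidden
    return ProjectionParams(
        Tensor(glorot(rng, e, h), requires_grad=True),
        Tensor(glorot(rng, h, e), requires_grad=True),
    )


def high_order_conv(
    h,
    powers: dict[int, np.ndarray],
    layer_weights: list[Tensor],
    orders: tuple[int, ...],
    activation: str | None = "tanh",
    layer_index: int = 0,
) -> Tensor:
    """One high-order layer: per-order propagate, transform, activate, concat."""
    h = Tensor.as_tensor(h)
    blocks = []
    for j, w in zip(orders, layer_weights):
        if h.shape[1] != w.shape[0]:
            raise ValueError(
                f"layer {layer_index}, order {j}: input width {h.shape[1]} "
                f"does not match weight rows {w.shape[0]}"
            )
        z = Tensor(powers[j]) @ h @ w if j > 0 else h @ w
        if activation == "tanh":
            z = z.tanh()
        elif activation is not None:
            raise ValueError(f"unknown activation {activation!r}")
        blocks.append(z)
    return concat(blocks, axis=1)


def encode(
    X,
    adj: np.ndarray | NormalizedAdjacency | dict[int, np.ndarray],
    params: EncoderParams,
    cfg: EncoderConfig,
) -> Tensor:
    """Full encoder forward pass: stacked high-order layers with tanh."""
    if isinstance(adj, dict):
        powers = adj
    else:
        norm = adj if isinstance(adj, NormalizedAdjacency) else normalize_adjacency(adj)
        powers = adjacency_powers(norm, cfg.orders)
    h = Tensor.as_tensor(X)
    for l, layer_weights in enumerate(params.weights):
        h = high_order_conv(h, powers, layer_weights, cfg.orders, "tanh", l)
    if not np.all(np.isfinite(h.data)):
        raise FloatingPointError(
            "encoder produced non-finite embeddings (exploding weights?)"
        )
    return h


def dual_encode(
    features: np.ndarray,
    adjacency: np.ndarray,
    params_out: EncoderParams,
    params_in: EncoderParams,
    cfg: EncoderConfig,
    view_id: int | str = "clean",
) -> tuple[Tensor, Tensor]:
    """Encode both gene roles: out on A, in on A^T (normalized after transpose)."""
    powers_out = adjacency_powers(normalize_adjacency(adjacency, view_id), cfg.orders)
    powers_in = adjacency_powers(normalize_adjacency(adjacency.T, view_id), cfg.orders)
    h_out = encode(features, powers_out, params_out, cfg)
    h_in = encode(features, powers_in, params_in, cfg)
    return h_out, h_in


def project(h, params: ProjectionParams) -> Tensor:
    """Two-layer projection head: ELU(h W1) W2, same output width as input."""
    h = Tensor.as_tensor(h)
    return (h @ params.w1).elu() @ params.w2
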