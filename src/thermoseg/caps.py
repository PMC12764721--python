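"""Capsule feature extraction with iterative dynamic routing.

A capsule is a vector-valued unit whose norm encodes the probability that an
entity is present and whose orientation encodes its pose.  Primary capsules
are formed by a 1x1 convolution over the segmenter's bottleneck feature map
followed by reshaping into pose vectors and squashing.  Upper capsules are
computed by routing-by-agreement: each primary capsule i casts a prediction
Yhat_ij = W_j U_i for every output capsule j, coupling coefficients D_ij
(a softmax over j of agreement logits b_ij) weight the predictions into
S_j = sum_i D_ij Yhat_ij, and the squashed output G_j = squash(S_j) feeds the
agreement update b_ij += Yhat_ij . G_j.  Transformation matrices are shared
across primary capsules ("global parameter sharing") to keep the parameter
count small.  The final capsule poses are reduced by a fully connected layer
and flattened into a single feature vector Z.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "CapsConfig",
    "CapsuleTensor",
    "squash",
    "PrimaryCapsules",
    "DynamicRouting",
    "CapsuleExtractor",
    "dynamic_routing",
]

_EPS = 1e-12


@dataclass
class CapsConfig:
    n_primary: int = 16
    primary_dim: int = 8
    n_out: int = 4
    out_dim: int = 8
    routing_iters: int = 3
    feature_len: int = 16
    share_weights: bool = True
    use_mask_channel: bool = True  # append pooled predicted-lesion probability

    def __post_init__(self):
        for name in ("n_primary", "primary_dim", "n_out", "out_dim",
                     "routing_iters", "feature_len"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")


@dataclass
class CapsuleTensor:
    """Routing state for inspection: inputs U, predictions Yhat, weighted sums
    S, coupling coefficients D (per iteration), and squashed outputs G."""

    U: np.ndarray
    Yhat: np.ndarray
    S: np.ndarray
    D: list[np.ndarray]
    G: np.ndarray


def squash(v, axis: int = -1):
    """Norm-bounding nonlinearity: (||v||^2 / (1 + ||v||^2)) * v / ||v||.

    Preserves direction, maps length into [0, 1); squash(0) = 0.  Accepts
    either an ndarray or a Tensor and returns the matching kind.
    """
    if isinstance(v, Tensor):
        sq = (v * v).sum(axis=axis, keepdims=True)
        scale = sq / (1.0 + sq) / (sq + _EPS).sqrt()
        return v * scale
    v = np.asarray(v, dtype=np.float64)
    sq = (v * v).sum(axis=axis, keepdims=True)
    return v * (sq / (1.0 + sq) / np.sqrt(sq + _EPS))


class PrimaryCapsules(nn.Module):
    """Feature map -> squashed primary capsule poses (B, n_primary, dim)."""

    def __init__(self, in_ch: int, spatial: int, cfg: CapsConfig,
                 rng: np.random.Generator):
        super().__init__()
        total = cfg.n_primary * cfg.primary_dim
        flat = spatial * spatial
        if total % flat:
            raise ValueError(
                f"n_primary * primary_dim = {total} must be divisible by the "
                f"feature map's {flat} spatial positions")
        self.cfg = cfg
        self.conv = nn.Linear(in_ch, total // flat, rng)  # 1x1 convolution

    def forward(self, fmap: Tensor) -> Tensor:
        b = fmap.shape[0]
        x = self.conv(fmap)
        x = x.reshape(b, self.cfg.n_primary, self.cfg.primary_dim)
        return squash(x)


def dynamic_routing(U: Tensor, W: Tensor, routing_iters: int,
                    record: CapsuleTensor | None = None) -> Tensor:
    """Routing-by-agreement between capsule layers.

    ``U`` is (B, n_in, d_in); ``W`` is (n_in, n_out, d_out, d_in) or, with
    shared weights, (1, n_out, d_out, d_in).  Agreement logits start at zero,
    so a single iteration reduces to uniform coupling.  Returns G of shape
    (B, n_out, d_out).
    """
    if routing_iters < 1:
        raise ValueError(f"routing_iters must be >= 1, got {routing_iters}")
    U = nn.as_tensor(U)
    W = nn.as_tensor(W)
    b, n_in, d_in = U.shape
    _, n_out, d_out, _ = W.shape
    # Yhat[b,i,j,:] = W[i,j] @ U[b,i]
    u = U.reshape(b, n_in, 1, d_in, 1)
    yhat = (W @ u).reshape(b, n_in, n_out, d_out)
    logits = np.zeros((b, n_in, n_out))
    ds = []
    G = None
    for it in range(routing_iters):
        shifted = logits - logits.max(axis=2, keepdims=True)
        e = np.exp(shifted)
        D = e / e.sum(axis=2, keepdims=True)  # couplings, softmax over j
        ds.append(D)
        S = (yhat * Tensor(D[..., None])).sum(axis=1)  # (B, n_out, d_out)
        G = squash(S)
        if it < routing_iters - 1:
            # agreement update outside the autodiff graph, as is conventional
            agree = np.einsum("bijd,bjd->bij", yhat.data.reshape(b, n_in, n_out, d_out),
                              G.data)
            logits = logits + agree
    if record is not None:
        record.U = U.data
        record.Yhat = yhat.data
        record.S = S.data
        record.D = ds
        record.G = G.data
    return G


class DynamicRouting(nn.Module):
    """Learned transformation matrices plus the routing procedure."""

    def __init__(self, cfg: CapsConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        n_w = 1 if cfg.share_weights else cfg.n_primary
        scale = 1.0 / np.sqrt(cfg.primary_dim)
        self.W = nn.Parameter(
            rng.normal(0.0, scale, (n_w, cfg.n_out, cfg.out_dim, cfg.primary_dim)))

    def forward(self, U: Tensor) -> Tensor:
        return dynamic_routing(U, self.W, self.cfg.routing_iters)


class CapsuleExtractor(nn.Module):
    """Primary capsules -> routed capsules -> flattened feature vector Z."""

    def __init__(self, in_ch: int, spatial: int, cfg: CapsConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.primary = PrimaryCapsules(in_ch, spatial, cfg, rng)
        self.routing = DynamicRouting(cfg, rng)
        self.reduce = nn.Linear(cfg.n_out * cfg.out_dim, cfg.feature_len, rng)

    def forward(self, fmap: Tensor) -> Tensor:
        U = self.primary(fmap)
        G = self.routing(U)
        return self.capsule_features(G)

    def capsule_features(self, G: Tensor) -> Tensor:
        """Fully connected reduction + flatten of routed capsule poses."""
        b = G.shape[0]
        return self.reduce(G.reshape(b, -1))
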