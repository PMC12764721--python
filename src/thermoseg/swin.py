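"""Windowed-attention primitives: patch embedding and merging, (shifted-)
window multi-head self-attention, hybrid channel-spatial window attention,
and the transformer blocks built from them.

Feature maps are channels-last tensors (batch, height, width, channels).
Window attention computes multi-head scaled dot-product attention
independently inside non-overlapping ``window x window`` tiles, with a
learned relative position bias added to the logits.  When ``shift > 0`` the
map is cyclically rolled by ``shift`` pixels before tiling and an additive
mask removes attention between tokens that were not spatial neighbours
before the roll (the standard shifted-window scheme).

The hybrid channel-spatial attention (SW-HCMA) gates each shifted window by
a per-window channel gate (a shared two-layer MLP over average- and
max-pooled channel descriptors) and a spatial gate (a convolution over the
channelwise average/max maps); both gates are sigmoid-squashed into (0, 1)
and applied multiplicatively.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "AttnKind",
    "NormKind",
    "SwinBlockConfig",
    "FeatureMap",
    "PatchEmbed",
    "PatchMerging",
    "WindowAttention",
    "HcmaAttention",
    "SwinBlock",
    "window_attention",
    "hcma_attention",
    "swin_block",
    "window_partition",
    "window_reverse",
    "patch_partition",
    "patch_merging",
    "shift_attention_mask",
]

#: additive logit for forbidden token pairs; exp() underflows to exactly 0
MASK_NEG = -1e9


class AttnKind(str, enum.Enum):
    W_MHSA = "W_MHSA"
    SW_MHSA = "SW_MHSA"
    SW_HCMA = "SW_HCMA"


class NormKind(str, enum.Enum):
    LAYER_NORM = "layer_norm"
    BATCH_NORM = "batch_norm"


@dataclass
class SwinBlockConfig:
    dim: int
    heads: int
    window: int
    shift: int = 0
    mlp_ratio: float = 4.0
    norm_kind: NormKind = NormKind.LAYER_NORM
    attn_kind: AttnKind = AttnKind.W_MHSA
    dropout: float = 0.0

    def __post_init__(self):
        self.norm_kind = NormKind(self.norm_kind)
        self.attn_kind = AttnKind(self.attn_kind)
        if self.dim % self.heads != 0:
            raise ValueError(f"dim {self.dim} not divisible by heads {self.heads}")
        if not 0 <= self.shift < self.window:
            raise ValueError(f"shift must satisfy 0 <= shift < window, "
                             f"got shift={self.shift}, window={self.window}")


@dataclass
class FeatureMap:
    """A (batch, height, width, channels) activation tensor with its stage."""

    data: Tensor
    stage: int = 0

    @property
    def shape(self):
        return self.data.shape


# ---------------------------------------------------------------------------
# window bookkeeping
# ---------------------------------------------------------------------------

def window_partition(x: Tensor, ws: int) -> Tensor:
    """(B, H, W, C) -> (B * nWindows, ws*ws, C) over non-overlapping tiles."""
    b, h, w, c = x.shape
    if h % ws or w % ws:
        raise ValueError(f"spatial dims ({h}, {w}) not divisible by window {ws}")
    x = x.reshape(b, h // ws, ws, w // ws, ws, c)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(-1, ws * ws, c)


def window_reverse(windows: Tensor, ws: int, h: int, w: int) -> Tensor:
    """Inverse of :func:`window_partition`."""
    nw = (h // ws) * (w // ws)
    b = windows.shape[0] // nw
    c = windows.shape[-1]
    x = windows.reshape(b, h // ws, w // ws, ws, ws, c)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(b, h, w, c)


def shift_attention_mask(h: int, w: int, ws: int, shift: int) -> np.ndarray:
    """Additive attention mask (nWindows, N, N) for a cyclic roll by ``shift``.

    Token pairs originating from opposite sides of the rolled boundary get
    ``MASK_NEG``; genuine neighbours get 0.
    """
    region = np.zeros((h, w))
    cnt = 0
    for hs in (slice(0, -ws), slice(-ws, -shift), slice(-shift, None)):
        for vs in (slice(0, -ws), slice(-ws, -shift), slice(-shift, None)):
            region[hs, vs] = cnt
            cnt += 1
    region = region.reshape(1, h, w, 1)
    win = window_partition(Tensor(region), ws).numpy()[..., 0]  # (nW, N)
    diff = win[:, :, None] - win[:, None, :]
    return np.where(diff == 0, 0.0, MASK_NEG)


# ---------------------------------------------------------------------------
# patch operations
# ---------------------------------------------------------------------------

class PatchEmbed(nn.Module):
    """Non-overlapping patch tokenization with a learned linear embedding."""

    def __init__(self, patch_size: int, in_ch: int, embed_dim: int,
                 rng: np.random.Generator):
        super().__init__()
        self.patch_size = patch_size
        self.in_ch = in_ch
        self.proj = nn.Linear(patch_size * patch_size * in_ch, embed_dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        b, h, w, c = x.shape
        p = self.patch_size
        if h % p or w % p:
            raise ValueError(
                f"image dims ({h}, {w}) must be divisible by patch size {p}")
        x = x.reshape(b, h // p, p, w // p, p, c)
        x = x.transpose(0, 1, 3, 2, 4, 5).reshape(b, h // p, w // p, p * p * c)
        return self.proj(x)


def patch_partition(image_batch, patch_size: int, embed_dim: int,
                    rng: np.random.Generator | None = None,
                    embed: PatchEmbed | None = None) -> FeatureMap:
    """Tokenize an image batch into a stage-0 feature map.

    Either pass a prebuilt :class:`PatchEmbed` or an ``rng`` to build one.
    """
    if embed is None:
        if rng is None:
            raise ValueError("provide either `embed` or `rng`")
        in_ch = image_batch.shape[-1] if np.ndim(image_batch) == 4 else 1
        embed = PatchEmbed(patch_size, in_ch, embed_dim, rng)
    x = nn.as_tensor(image_batch)
    if x.ndim == 3:
        x = x.reshape(*x.shape, 1)
    return FeatureMap(embed(x), stage=0)


class PatchMerging(nn.Module):
    """Concatenate 2x2 token neighbourhoods (4C) and project to 2C."""

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        self.dim = dim
        self.proj = nn.Linear(4 * dim, 2 * dim, rng, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        b, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial dims ({h}, {w}) must be even for merging")
        x = x.reshape(b, h // 2, 2, w // 2, 2, c)
        x = x.transpose(0, 1, 3, 2, 4, 5).reshape(b, h // 2, w // 2, 4 * c)
        return self.proj(x)


def patch_merging(x, rng: np.random.Generator | None = None,
                  merge: PatchMerging | None = None) -> FeatureMap:
    """Functional wrapper over :class:`PatchMerging`."""
    fm = x if isinstance(x, FeatureMap) else FeatureMap(nn.as_tensor(x))
    if merge is None:
        if rng is None:
            raise ValueError("provide either `merge` or `rng`")
        merge = PatchMerging(fm.shape[-1], rng)
    return FeatureMap(merge(fm.data), stage=fm.stage + 1)


# ---------------------------------------------------------------------------
# attention operators
# ---------------------------------------------------------------------------

def _relative_index(ws: int) -> np.ndarray:
    """Index into the (2ws-1)^2 bias table for every token pair in a window."""
    coords = np.stack(np.meshgrid(np.arange(ws), np.arange(ws), indexing="ij"))
    coords = coords.reshape(2, -1)
    rel = coords[:, :, None] - coords[:, None, :]  # (2, N, N)
    rel = rel + (ws - 1)
    return rel[0] * (2 * ws - 1) + rel[1]


class WindowAttention(nn.Module):
    """Multi-head self-attention within (optionally shifted) windows."""

    def __init__(self, cfg: SwinBlockConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.qkv = nn.Linear(cfg.dim, 3 * cfg.dim, rng)
        self.proj = nn.Linear(cfg.dim, cfg.dim, rng)
        ws = cfg.window
        self.bias_table = nn.Parameter(
            rng.normal(0.0, 0.02, ((2 * ws - 1) ** 2, cfg.heads)))
        self._rel_index = _relative_index(ws)
        self._mask_cache: dict[tuple, np.ndarray] = {}

    def attention_weights(self, x: Tensor) -> np.ndarray:
        """Softmax attention maps (B*nW, heads, N, N) for inspection/tests."""
        _, attn = self._attend(x, return_weights=True)
        return attn.numpy()

    def _attend(self, x: Tensor, return_weights: bool = False):
        cfg = self.cfg
        b, h, w, c = x.shape
        ws, shift = cfg.window, cfg.shift
        if h % ws or w % ws:
            raise ValueError(f"spatial dims ({h}, {w}) not divisible by window {ws}")
        if shift > 0:
            x = nn.roll(x, (-shift, -shift), (1, 2))
        windows = window_partition(x, ws)  # (B*nW, N, C)
        n = ws * ws
        heads, dh = cfg.heads, c // cfg.heads
        qkv = self.qkv(windows).reshape(-1, n, 3, heads, dh)
        qkv = qkv.transpose(2, 0, 3, 1, 4)  # (3, B*nW, heads, N, dh)
        q, k, v = qkv[0], qkv[1], qkv[2]
        logits = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        bias = nn.take(self.bias_table, self._rel_index)  # (N, N, heads)
        logits = logits + bias.transpose(2, 0, 1)
        if shift > 0:
            key = (h, w, ws, shift)
            if key not in self._mask_cache:
                self._mask_cache[key] = shift_attention_mask(h, w, ws, shift)
            mask = self._mask_cache[key]  # (nW, N, N)
            nw = mask.shape[0]
            logits = logits.reshape(b, nw, heads, n, n) + Tensor(mask[None, :, None])
            logits = logits.reshape(b * nw, heads, n, n)
        attn = nn.softmax(logits, axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(-1, n, c)
        out = self.proj(out)
        out = window_reverse(out, ws, h, w)
        if shift > 0:
            out = nn.roll(out, (shift, shift), (1, 2))
        return out, (attn if return_weights else None)

    def forward(self, x: Tensor) -> Tensor:
        out, _ = self._attend(x)
        return out


class HcmaAttention(nn.Module):
    """Hybrid channel-spatial gating within shifted windows (SW-HCMA)."""

    def __init__(self, cfg: SwinBlockConfig, rng: np.random.Generator,
                 reduction: int = 4, spatial_kernel: int = 3):
        super().__init__()
        self.cfg = cfg
        hidden = max(cfg.dim // reduction, 1)
        self.ch_fc1 = nn.Linear(cfg.dim, hidden, rng)
        self.ch_fc2 = nn.Linear(hidden, cfg.dim, rng)
        self.spatial_conv = nn.Conv2d(2, 1, spatial_kernel, rng,
                                      padding=spatial_kernel // 2)

    def forward(self, x: Tensor) -> Tensor:
        cfg = self.cfg
        b, h, w, c = x.shape
        ws, shift = cfg.window, cfg.shift
        if shift > 0:
            x = nn.roll(x, (-shift, -shift), (1, 2))
        windows = window_partition(x, ws)  # (B*nW, N, C)
        n = ws * ws
        # channel gate: shared MLP over pooled descriptors
        avg_desc = windows.mean(axis=1)
        max_desc = windows.amax(axis=1)
        gate_logit = (self.ch_fc2(self.ch_fc1(avg_desc).relu())
                      + self.ch_fc2(self.ch_fc1(max_desc).relu()))
        ch_gate = gate_logit.sigmoid().reshape(-1, 1, c)
        gated = windows * ch_gate
        # spatial gate: conv over channelwise avg/max maps
        avg_map = gated.mean(axis=-1, keepdims=True)
        max_map = gated.amax(axis=-1, keepdims=True)
        desc = nn.concatenate([avg_map, max_map], axis=-1)
        desc = desc.reshape(-1, ws, ws, 2)
        sp_gate = self.spatial_conv(desc).sigmoid().reshape(-1, n, 1)
        out = gated * sp_gate
        out = window_reverse(out, ws, h, w)
        if shift > 0:
            out = nn.roll(out, (shift, shift), (1, 2))
        return out


class SwinBlock(nn.Module):
    """Pre-norm residual transformer block.

    ``u = x + Attn(Norm(x)); out = u + MLP(Norm(u))`` where the attention is
    W-MHSA, SW-MHSA or SW-HCMA and the norm is LayerNorm (standard block) or
    BatchNorm (modified block).
    """

    def __init__(self, cfg: SwinBlockConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg

        def make_norm():
            if cfg.norm_kind is NormKind.LAYER_NORM:
                return nn.LayerNorm(cfg.dim)
            return nn.BatchNorm(cfg.dim)

        self.norm1 = make_norm()
        self.norm2 = make_norm()
        if cfg.attn_kind is AttnKind.SW_HCMA:
            self.attn = HcmaAttention(cfg, rng)
        else:
            if cfg.attn_kind is AttnKind.W_MHSA and cfg.shift != 0:
                raise ValueError("W_MHSA requires shift == 0")
            self.attn = WindowAttention(cfg, rng)
        hidden = int(round(cfg.mlp_ratio * cfg.dim))
        self.mlp = nn.Mlp(cfg.dim, hidden, rng, dropout=cfg.dropout)

    def forward(self, x: Tensor) -> Tensor:
        u = x + self.attn(self.norm1(x))
        return u + self.mlp(self.norm2(u))


def window_attention(x, cfg: SwinBlockConfig,
                     rng: np.random.Generator | None = None,
                     attn: WindowAttention | None = None) -> FeatureMap:
    """Functional wrapper over :class:`WindowAttention`."""
    fm = x if isinstance(x, FeatureMap) else FeatureMap(nn.as_tensor(x))
    if attn is None:
        if rng is None:
            raise ValueError("provide either `attn` or `rng`")
        attn = WindowAttention(cfg, rng)
    return FeatureMap(attn(fm.data), stage=fm.stage)


def hcma_attention(x, cfg: SwinBlockConfig,
                   rng: np.random.Generator | None = None,
                   attn: HcmaAttention | None = None) -> FeatureMap:
    """Functional wrapper over :class:`HcmaAttention`."""
    if cfg.attn_kind is not AttnKind.SW_HCMA:
        raise ValueError("hcma_attention requires attn_kind SW_HCMA")
    fm = x if isinstance(x, FeatureMap) else FeatureMap(nn.as_tensor(x))
    if attn is None:
        if rng is None:
            raise ValueError("provide either `attn` or `rng`")
        attn = HcmaAttention(cfg, rng)
    return FeatureMap(attn(fm.data), stage=fm.stage)


def swin_block(x, cfg: SwinBlockConfig, rng: np.random.Generator | None = None,
               block: SwinBlock | None = None) -> FeatureMap:
    """Functional wrapper over :class:`SwinBlock`."""
    fm = x if isinstance(x, FeatureMap) else FeatureMap(nn.as_tensor(x))
    if block is None:
        if rng is None:
            raise ValueError("provide either `block` or `rng`")
        block = SwinBlock(cfg, rng)
    return FeatureMap(block(fm.data), stage=fm.stage)
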