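"""U-shaped windowed-attention segmenter (U-MST).

A three-stage encoder (patch embedding, then two patch-merging
downsamplings, each stage a stack of transformer blocks), a multi-scale
feature-fusion module, and a mirrored three-stage decoder with skip
connections.  Spatial resolution halves and channel width doubles at each
encoder stage; the segmentation head undoes the initial patching with a
learned patch expansion and refines the full-resolution map with a small
convolution over the expanded features and the raw input image.

Fusion follows the "downsample-and-concatenate" rule: each stage map is
reduced with a 2x2 stride-2 convolution and concatenated channelwise with
the following stage, then linearly projected back to that stage's width, so
that shallow detail reaches the deeper representations that feed the decoder.

Training minimizes a soft Dice loss on the foreground probability map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .swin import (
    AttnKind,
    FeatureMap,
    NormKind,
    PatchEmbed,
    PatchMerging,
    SwinBlock,
    SwinBlockConfig,
)

__all__ = ["UmstConfig", "SegOutput", "Umst", "dice_loss"]


@dataclass
class UmstConfig:
    stages: int = 3
    embed_dim: int = 32
    depths: tuple[int, ...] = (2, 2, 2)
    patch_size: int = 4
    window: int = 4
    heads: tuple[int, ...] = (2, 2, 4)
    mlp_ratio: float = 2.0
    n_seg_classes: int = 2
    norm_kind: NormKind = NormKind.BATCH_NORM
    use_hcma: bool = True
    use_fusion: bool = True
    dropout: float = 0.0

    def __post_init__(self):
        self.norm_kind = NormKind(self.norm_kind)
        if self.stages != 3:
            raise ValueError(f"the architecture is fixed at 3 stages, got {self.stages}")
        if len(self.depths) != self.stages:
            raise ValueError(f"depths must have {self.stages} entries, got {self.depths}")
        if len(self.heads) != self.stages:
            raise ValueError(f"heads must have {self.stages} entries, got {self.heads}")
        if self.n_seg_classes < 2:
            raise ValueError("n_seg_classes must be >= 2")

    @property
    def stage_dims(self) -> tuple[int, ...]:
        return tuple(self.embed_dim * 2 ** i for i in range(self.stages))

    def min_image_size(self) -> int:
        return self.patch_size * 2 ** (self.stages - 1) * self.window

    def validate_image_size(self, size: int):
        div = self.patch_size * 2 ** (self.stages - 1)
        if size % div:
            raise ValueError(
                f"image size {size} must be divisible by patch_size * 2^(stages-1) = {div}")


@dataclass
class SegOutput:
    """Full-resolution class logits and the thresholded binary mask."""

    logits: np.ndarray  # (B, H, W, n_seg_classes)
    mask: np.ndarray    # (B, H, W) in {0, 1}

    def __post_init__(self):
        self.logits = np.asarray(self.logits)
        self.mask = np.asarray(self.mask)


def _make_stage(dim: int, depth: int, heads: int, cfg: UmstConfig,
                grid: int, rng: np.random.Generator) -> list[SwinBlock]:
    """A stack of blocks alternating unshifted and shifted attention.

    Even blocks use plain window attention; odd blocks shift by half a
    window and, when enabled, use the hybrid channel-spatial attention.
    The shift is dropped when the token grid is no larger than one window.
    """
    blocks = []
    for i in range(depth):
        shifted = (i % 2 == 1) and grid > cfg.window
        if i % 2 == 0:
            kind = AttnKind.W_MHSA
        else:
            kind = AttnKind.SW_HCMA if cfg.use_hcma else AttnKind.SW_MHSA
            if kind is AttnKind.SW_MHSA and not shifted:
                kind = AttnKind.W_MHSA
        blk_cfg = SwinBlockConfig(
            dim=dim, heads=heads, window=cfg.window,
            shift=cfg.window // 2 if shifted else 0,
            mlp_ratio=cfg.mlp_ratio, norm_kind=cfg.norm_kind,
            attn_kind=kind, dropout=cfg.dropout)
        blocks.append(SwinBlock(blk_cfg, rng))
    return blocks


class Umst(nn.Module):
    """The segmentation network; ``forward`` maps images to logits."""

    def __init__(self, cfg: UmstConfig, rng: np.random.Generator,
                 image_size: int = 64, in_ch: int = 1):
        super().__init__()
        cfg.validate_image_size(image_size)
        self.cfg = cfg
        self.image_size = image_size
        self._in_ch = in_ch
        dims = cfg.stage_dims
        grid = image_size // cfg.patch_size

        self.embed = PatchEmbed(cfg.patch_size, in_ch, dims[0], rng)
        self.enc_stages = []
        self.mergers = []
        g = grid
        for s in range(cfg.stages):
            if s > 0:
                self.mergers.append(PatchMerging(dims[s - 1], rng))
                g //= 2
            self.enc_stages.append(
                _make_stage(dims[s], cfg.depths[s], cfg.heads[s], cfg, g, rng))

        # fusion: downsample stage s, concat with stage s+1, project back
        self.fuse_down = [nn.Conv2d(dims[s], dims[s], 2, rng, stride=2)
                          for s in range(cfg.stages - 1)]
        self.fuse_proj = [nn.Linear(dims[s] + dims[s + 1], dims[s + 1], rng)
                          for s in range(cfg.stages - 1)]

        # decoder: bottleneck block, then two upsample+skip stages
        self.dec_bottleneck = _make_stage(dims[2], 1, cfg.heads[2], cfg,
                                          grid // 4, rng)
        self.dec_proj = [
            nn.Linear(dims[2] + dims[1], dims[1], rng),
            nn.Linear(dims[1] + dims[0], dims[0], rng),
        ]
        self.dec_stages = [
            _make_stage(dims[1], 1, cfg.heads[1], cfg, grid // 2, rng),
            _make_stage(dims[0], 1, cfg.heads[0], cfg, grid, rng),
        ]
        # final norm keeps head logits well-scaled (prevents softmax saturation)
        self.final_norm = nn.LayerNorm(dims[0])
        # patch-expansion head: per-token linear map to patch_size^2 sub-pixel
        # feature blocks (undoing the initial patching), then a full-resolution
        # refinement conv over [expanded features, raw image] for crisp borders
        self.expand_ch = 8
        self.head_expand = nn.Linear(dims[0],
                                     cfg.patch_size ** 2 * self.expand_ch, rng)
        self.refine = nn.Conv2d(self.expand_ch + in_ch, self.expand_ch, 3, rng,
                                padding=1)
        self.head = nn.Linear(self.expand_ch, cfg.n_seg_classes, rng)

    # -- pipeline pieces -----------------------------------------------------
    def encode(self, images) -> list[FeatureMap]:
        """Per-stage feature maps for an image batch (B, H, W[, 1])."""
        x = nn.as_tensor(images)
        if x.ndim == 3:
            x = x.reshape(*x.shape, 1)
        x = self.embed(x)
        maps = []
        for s in range(self.cfg.stages):
            if s > 0:
                x = self.mergers[s - 1](x)
            for blk in self.enc_stages[s]:
                x = blk(x)
            maps.append(FeatureMap(x, stage=s))
        return maps

    def fuse_features(self, stage_maps: list[FeatureMap]) -> list[FeatureMap]:
        """Multi-scale fusion, shallow to deep; identity when disabled."""
        if not self.cfg.use_fusion:
            return list(stage_maps)
        fused = [stage_maps[0]]
        for s in range(self.cfg.stages - 1):
            down = self.fuse_down[s](fused[-1].data)
            cat = nn.concatenate([down, stage_maps[s + 1].data], axis=-1)
            fused.append(FeatureMap(self.fuse_proj[s](cat), stage=s + 1))
        return fused

    def decode(self, fused_maps: list[FeatureMap], images=None,
               zero_skips: bool = False) -> Tensor:
        """Decoder trunk; returns full-resolution logits as a Tensor.

        ``images`` (the network input) feeds the full-resolution refinement
        conv; when omitted, a zero stem is used.
        """
        x = fused_maps[-1].data
        for blk in self.dec_bottleneck:
            x = blk(x)
        self._bottleneck = x  # cached for downstream feature extraction
        for i, skip_fm in enumerate((fused_maps[1], fused_maps[0])):
            x = nn.upsample_nearest2d(x, 2)
            skip = skip_fm.data
            if zero_skips:
                skip = Tensor(np.zeros(skip.shape))
            x = nn.concatenate([x, skip], axis=-1)
            x = self.dec_proj[i](x)
            for blk in self.dec_stages[i]:
                x = blk(x)
        x = self.final_norm(x)
        x = self.head_expand(x)  # (B, h, w, p*p*expand_ch)
        b, h, w, _ = x.shape
        p, ec = self.cfg.patch_size, self.expand_ch
        x = x.reshape(b, h, w, p, p, ec)
        x = x.transpose(0, 1, 3, 2, 4, 5).reshape(b, h * p, w * p, ec)
        if images is None:
            stem = Tensor(np.zeros((b, h * p, w * p, self._in_ch)))
        else:
            stem = nn.as_tensor(images)
            if stem.ndim == 3:
                stem = stem.reshape(*stem.shape, 1)
        x = nn.concatenate([x, stem], axis=-1)
        x = nn.gelu(self.refine(x)) + x[..., :ec]  # residual refinement
        return self.head(x)

    def forward(self, images, zero_skips: bool = False) -> Tensor:
        return self.decode(self.fuse_features(self.encode(images)),
                           images=images, zero_skips=zero_skips)

    def bottleneck_features(self) -> Tensor:
        """Deepest decoder activation from the most recent forward pass."""
        if not hasattr(self, "_bottleneck"):
            raise RuntimeError("run a forward pass first")
        return self._bottleneck

    def segment(self, images) -> SegOutput:
        """Predict binary masks for a batch (no gradient bookkeeping)."""
        was_training = self.training
        self.eval()
        try:
            logits = self.forward(images).numpy()
        finally:
            self.train(was_training)
        mask = (logits.argmax(axis=-1) > 0).astype(np.uint8)
        return SegOutput(logits=logits, mask=mask)


def dice_loss(logits: Tensor, target_mask, eps: float = 1.0) -> Tensor:
    """1 - soft Dice on the foreground probability map.

    ``logits`` is (B, H, W, classes); ``target_mask`` is a binary (B, H, W)
    array.  The smoothing term ``eps`` keeps the loss finite for
    all-background targets.
    """
    target = np.asarray(target_mask, dtype=np.float64)
    if logits.shape[:-1] != target.shape:
        raise ValueError(
            f"logits spatial shape {logits.shape[:-1]} != mask shape {target.shape}")
    probs = nn.softmax(logits, axis=-1)
    fg = probs[..., 1] if logits.shape[-1] == 2 else 1.0 - probs[..., 0]
    t = Tensor(target)
    inter = (fg * t).sum()
    denom = fg.sum() + t.sum()
    dice = (2.0 * inter + eps) / (denom + eps)
    return 1.0 - dice
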