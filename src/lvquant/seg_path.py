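"""U-Net-like 3D hybrid CNN-Transformer segmentation path.

A residual 3D convolutional stem with three downsampling stages (group norm,
randomized leaky ReLU, 1x2x2 max pooling — the slice axis is never pooled)
reduces an (1, 5, 80, 80) window to a feature grid; a strided 1x2x2 patch
embedding brings it to (hidden, 5, 5, 5), whose 125 cells become the token
sequence of a pre-norm ViT-style encoder.  A cascaded upsampler of 1x2x2
transposed convolutions, concatenating the matching pre-pooling stem skip at
each scale, restores full resolution and emits 3-class logits for all five
slices.  The decoder's intermediate multi-scale feature maps are exposed for
the regression path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .autodiff import Tensor, concatenate, maxpool3d_hw2

__all__ = ["SegConfig", "SegPath"]


@dataclass
class SegConfig:
    in_channels: int = 1
    n_classes: int = 3
    image_size: int = 80
    n_slices: int = 5
    stem_channels: tuple = (32, 64, 128)
    convs_per_stage: int = 2
    hidden: int = 256
    depth: int = 4
    heads: int = 8
    mlp_ratio: int = 4
    decoder_channels: tuple = (128, 64, 32, 16)
    norm_groups: int = 8

    def __post_init__(self):
        # three pooled stages + the stride-2 patch embedding: /16 overall
        if self.image_size % 16:
            raise ValueError("image size must be divisible by 16")
        if len(self.stem_channels) != 3 or len(self.decoder_channels) != 4:
            raise ValueError("expected 3 stem stages and 4 decoder stages")
        if self.hidden % self.heads:
            raise ValueError("hidden size must divide into heads")

    @property
    def token_grid(self) -> tuple:
        g = self.image_size // 16
        return (self.n_slices, g, g)

    @property
    def n_tokens(self) -> int:
        d, h, w = self.token_grid
        return d * h * w

    @classmethod
    def small(cls, image_size: int = 80) -> "SegConfig":
        """Desk-scale configuration for CPU training runs."""
        return cls(image_size=image_size, stem_channels=(4, 8, 16),
                   convs_per_stage=1, hidden=32, depth=1, heads=4,
                   mlp_ratio=2, decoder_channels=(16, 8, 8, 4), norm_groups=2)


def _groups(requested: int, channels: int) -> int:
    g = min(requested, channels)
    while channels % g:
        g -= 1
    return g


class _StemStage(nn.Module):
    """Residual conv stage: conv(+conv) with group norm and randomized
    leaky activations, plus a 1x1x1 projection shortcut when widths differ."""

    def __init__(self, cin, cout, norm_groups, convs=2):
        super().__init__()
        self.blocks = []
        c = cin
        for _ in range(convs):
            self.blocks.append(nn.Conv3d(c, cout, 3, padding=(1, 1, 1)))
            self.blocks.append(nn.GroupNorm(_groups(norm_groups, cout), cout))
            c = cout
        self.proj = nn.Conv3d(cin, cout, 1) if cin != cout else None
        self.acts = [nn.RReLU() for _ in range(convs)]

    def forward(self, x):
        h = x
        n = len(self.acts)
        for i in range(n):
            h = self.blocks[2 * i + 1](self.blocks[2 * i](h))
            if i < n - 1:
                h = self.acts[i](h)
        h = h + (self.proj(x) if self.proj is not None else x)
        return self.acts[-1](h)


class _DecoderStage(nn.Module):
    """1x2x2 transposed-conv upsampling, optional skip concat, fuse conv."""

    def __init__(self, cin, cout, skip_channels, norm_groups):
        super().__init__()
        self.up = nn.ConvTranspose3d(cin, cout, stride=(1, 2, 2))
        self.fuse = nn.Conv3d(cout + skip_channels, cout, 3, padding=(1, 1, 1))
        self.norm = nn.GroupNorm(_groups(norm_groups, cout), cout)
        self.act = nn.RReLU()

    def forward(self, x, skip=None):
        h = self.up(x)
        if skip is not None:
            h = concatenate([h, skip], axis=1)
        return self.act(self.norm(self.fuse(h)))


class SegPath(nn.Module):
    def __init__(self, config: SegConfig | None = None, init_rng=None):
        super().__init__()
        self.config = cfg = config or SegConfig()
        if init_rng is not None:
            nn.set_init_rng(init_rng)
        c1, c2, c3 = cfg.stem_channels
        self.stage1 = _StemStage(cfg.in_channels, c1, cfg.norm_groups, cfg.convs_per_stage)
        self.stage2 = _StemStage(c1, c2, cfg.norm_groups, cfg.convs_per_stage)
        self.stage3 = _StemStage(c2, c3, cfg.norm_groups, cfg.convs_per_stage)
        # patch embedding reconciles the stem's /8 with the printed 5x5x5 grid
        self.embed = nn.Conv3d(c3, cfg.hidden, (1, 2, 2), stride=(1, 2, 2))
        self.pos_embed = nn.Parameter(
            0.02 * nn._INIT_RNG.standard_normal((1, cfg.n_tokens, cfg.hidden)))
        self.encoder = [nn.TransformerBlock(cfg.hidden, cfg.heads, cfg.mlp_ratio)
                        for _ in range(cfg.depth)]
        d0, d1, d2, d3 = cfg.decoder_channels
        self.dec0 = _DecoderStage(cfg.hidden, d0, 0, cfg.norm_groups)    # 5 -> 10
        self.dec1 = _DecoderStage(d0, d1, c3, cfg.norm_groups)           # 10 -> 20
        self.dec2 = _DecoderStage(d1, d2, c2, cfg.norm_groups)           # 20 -> 40
        self.dec3 = _DecoderStage(d2, d3, c1, cfg.norm_groups)           # 40 -> 80
        self.head = nn.Conv3d(d3, cfg.n_classes, 1)

    # ------------------------------------------------------------------

    def stem_encode(self, x: Tensor):
        """Residual stem; returns the embedded feature grid and per-stage skips."""
        s1 = self.stage1(x)
        s2 = self.stage2(maxpool3d_hw2(s1))
        s3 = self.stage3(maxpool3d_hw2(s2))
        grid = self.embed(maxpool3d_hw2(s3))
        return grid, (s1, s2, s3)

    def transformer_encode(self, grid: Tensor) -> Tensor:
        """Flatten the grid to tokens, add positions, run the encoder blocks."""
        b, c = grid.shape[0], grid.shape[1]
        n = int(np.prod(grid.shape[2:]))
        if n != self.config.n_tokens:
            raise ValueError(f"got {n} tokens; configured for {self.config.n_tokens}")
        tokens = grid.reshape(b, c, n).transpose(0, 2, 1) + self.pos_embed
        for block in self.encoder:
            tokens = block(tokens)
        return tokens

    def decode(self, tokens: Tensor, skips):
        """Cascaded upsampling with skip concatenation; 3-class logits at full
        resolution plus the intermediate decoder features keyed by spatial size."""
        b = tokens.shape[0]
        d, gh, gw = self.config.token_grid
        grid = tokens.transpose(0, 2, 1).reshape(b, self.config.hidden, d, gh, gw)
        s1, s2, s3 = skips
        feats = {}
        h = self.dec0(grid)
        feats[h.shape[-1]] = h
        h = self.dec1(h, s3)
        feats[h.shape[-1]] = h
        h = self.dec2(h, s2)
        feats[h.shape[-1]] = h
        h = self.dec3(h, s1)
        feats[h.shape[-1]] = h
        return self.head(h), feats

    def forward(self, x: Tensor):
        """Returns (logits (B, 3, 5, H, W), decoder feature pyramid)."""
        grid, skips = self.stem_encode(x)
        tokens = self.transformer_encode(grid)
        return self.decode(tokens, skips)

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())
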