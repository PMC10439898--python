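"""Spatio-temporal regression path: 11 indices + phase for the center frame.

The path consumes the raw 5-frame window and, at each of its two scales, the
matching multi-scale decoder features of the segmentation path.  Building
blocks:

* RRA block — two recurrent-residual convolution units (one kernel-3 conv
  applied recurrently, input added back) followed by squeeze-and-excitation
  channel attention.
* Spatio-temporal block — an unpadded 3x1x1 temporal conv (slices shrink by
  two) then a padded 1x3x3 spatial conv, each with batch norm and ReLU, and
  a 1x2x2 max pool.  Two blocks collapse the five slices to one
  (5 -> 3 -> 1), so the output describes the central frame with a temporal
  receptive field covering the whole window.
* SE fusion — channel concatenation of the regression stream with the
  (temporally center-cropped) segmentation decoder features, squeeze-and-
  excitation over the joint channels, and a 1x1x1 conv back to the
  regression width.

Two heads finish the path: a shallow convolutional regressor (1x1x1 conv,
global average pooling, linear) for the 11 indices, and a 360-unit
perceptron with 2 output neurons for the systole/diastole phase.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import nn
from .autodiff import Tensor, concatenate, maxpool3d_hw2, relu

__all__ = ["RegConfig", "RRABlock", "STBlock", "SEFuse", "RegPath"]


@dataclass
class RegConfig:
    in_channels: int = 1
    width: int = 16            # channels after the stem; doubles per ST block
    stage_channels: tuple | None = None  # explicit (stem, post-ST1, post-ST2)
    recurrence: int = 2        # recurrent steps in each recurrent-residual unit
    se_reduction: int = 8
    phase_hidden: int = 360    # fixed-size phase MLP
    n_indices: int = 11
    clamp_indices: bool = False  # optional sigmoid clamp on the index outputs

    def __post_init__(self):
        if self.phase_hidden != 360:
            raise ValueError("the phase MLP is defined with 360 hidden units")
        if self.n_indices != 11:
            raise ValueError("the regressor emits exactly 11 indices")
        if self.stage_channels is not None and len(self.stage_channels) != 3:
            raise ValueError("stage_channels must name 3 stage widths")

    def stages(self) -> tuple:
        """Channel width at each stage; defaults to doubling per ST block."""
        if self.stage_channels is not None:
            return tuple(self.stage_channels)
        return (self.width, 2 * self.width, 4 * self.width)

    @classmethod
    def small(cls) -> "RegConfig":
        # the full-resolution stage stays narrow (it dominates CPU cost);
        # the pooled stages carry the capacity the index head needs
        return cls(width=4, stage_channels=(4, 16, 32),
                   recurrence=1, se_reduction=2)


class _RecurrentConvUnit(nn.Module):
    """One conv applied `T` times recurrently; the input is added back."""

    def __init__(self, channels, recurrence):
        super().__init__()
        self.conv = nn.Conv3d(channels, channels, 3, padding=(1, 1, 1))
        self.norms = [nn.BatchNorm3d(channels) for _ in range(recurrence)]

    def forward(self, x):
        z = x
        for norm in self.norms:
            z = relu(norm(self.conv(z)))
        return x + z


class RRABlock(nn.Module):
    """Two recurrent-residual conv units + squeeze-and-excitation; shape-preserving."""

    def __init__(self, channels, recurrence=2, se_reduction=8):
        super().__init__()
        self.unit1 = _RecurrentConvUnit(channels, recurrence)
        self.unit2 = _RecurrentConvUnit(channels, recurrence)
        self.se = nn.SqueezeExcite(channels, se_reduction)

    def forward(self, x):
        return self.se(self.unit2(self.unit1(x)))


class STBlock(nn.Module):
    """Temporal 3x1x1 conv (valid) -> spatial 1x3x3 conv (padded) -> 1x2x2 pool."""

    def __init__(self, cin, cout):
        super().__init__()
        self.temporal = nn.Conv3d(cin, cout, (3, 1, 1))
        self.bn1 = nn.BatchNorm3d(cout)
        self.spatial = nn.Conv3d(cout, cout, (1, 3, 3), padding=(0, 1, 1))
        self.bn2 = nn.BatchNorm3d(cout)

    def forward(self, x):
        if x.shape[2] < 3:
            raise ValueError("spatio-temporal block needs at least 3 slices")
        h = relu(self.bn1(self.temporal(x)))
        h = relu(self.bn2(self.spatial(h)))
        return maxpool3d_hw2(h)


class SEFuse(nn.Module):
    """Adaptive concatenation of segmentation-path features into the stream."""

    def __init__(self, reg_channels, seg_channels, se_reduction=8):
        super().__init__()
        joint = reg_channels + seg_channels
        self.se = nn.SqueezeExcite(joint, se_reduction)
        self.mix = nn.Conv3d(joint, reg_channels, 1)

    def forward(self, reg_feat, seg_feat):
        if seg_feat.shape[-2:] != reg_feat.shape[-2:]:
            raise ValueError(f"spatial grid mismatch: regression {reg_feat.shape} "
                             f"vs segmentation {seg_feat.shape}")
        d_reg, d_seg = reg_feat.shape[2], seg_feat.shape[2]
        if d_seg != d_reg:   # center-crop the slice axis of the seg features
            if d_seg < d_reg:
                raise ValueError("segmentation features have too few slices")
            ofs = (d_seg - d_reg) // 2
            seg_feat = seg_feat[:, :, ofs:ofs + d_reg]
        return self.mix(self.se(concatenate([reg_feat, seg_feat], axis=1)))


class RegPath(nn.Module):
    """The full regression path.

    `seg_feature_channels` maps the spatial sizes of the two fused scales
    (input_size/2 and input_size/4) to the channel width of the segmentation
    decoder features there.
    """

    def __init__(self, config: RegConfig | None = None,
                 seg_feature_channels: dict | None = None, init_rng=None):
        super().__init__()
        self.config = cfg = config or RegConfig()
        if init_rng is not None:
            nn.set_init_rng(init_rng)
        w1, w2, w3 = cfg.stages()
        self.stem = nn.Conv3d(cfg.in_channels, w1, 3, padding=(1, 1, 1))
        self.stem_bn = nn.BatchNorm3d(w1)
        self.rra1 = RRABlock(w1, cfg.recurrence, cfg.se_reduction)
        self.st1 = STBlock(w1, w2)
        self.rra2 = RRABlock(w2, cfg.recurrence, cfg.se_reduction)
        self.st2 = STBlock(w2, w3)
        self.rra3 = RRABlock(w3, cfg.recurrence, cfg.se_reduction)
        self.fuse1 = self.fuse2 = None
        if seg_feature_channels is not None:
            sizes = sorted(seg_feature_channels)   # [size/4, size/2]
            self.fuse1 = SEFuse(w2, seg_feature_channels[sizes[1]], cfg.se_reduction)
            self.fuse2 = SEFuse(w3, seg_feature_channels[sizes[0]], cfg.se_reduction)
        # shallow CNN regressor head
        self.head_conv = nn.Conv3d(w3, w3, 1)
        self.head_lin = nn.Linear(w3, cfg.n_indices)
        # phase classifier head
        self.phase_fc1 = nn.Linear(w3, cfg.phase_hidden)
        self.phase_fc2 = nn.Linear(cfg.phase_hidden, 2)

    def forward(self, window: Tensor, seg_features: dict | None = None):
        """(indices (B, 11), phase logits (B, 2)) for the center frame."""
        h = relu(self.stem_bn(self.stem(window)))
        h = self.rra1(h)
        h = self.st1(h)                                  # 5 slices -> 3, HW/2
        if self.fuse1 is not None and seg_features is not None:
            h = self.fuse1(h, seg_features[h.shape[-1]])
        h = self.rra2(h)
        h = self.st2(h)                                  # 3 slices -> 1, HW/4
        if self.fuse2 is not None and seg_features is not None:
            h = self.fuse2(h, seg_features[h.shape[-1]])
        h = self.rra3(h)
        pooled = relu(self.head_conv(h)).mean(axis=(2, 3, 4))   # (B, 4w)
        indices = self.head_lin(pooled)
        if self.config.clamp_indices:
            from .autodiff import sigmoid
            indices = sigmoid(indices)
        phase_logits = self.phase_fc2(relu(self.phase_fc1(h.mean(axis=(2, 3, 4)))))
        return indices, phase_logits

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())
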