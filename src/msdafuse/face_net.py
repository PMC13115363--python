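"""Multi-scale dilated-attention CNN for facial expression recognition.

The full model (MSDAC) is: two conv blocks (stem) -> a parallel three-branch
multi-scale dilated convolution module (MSDC; 3x3 kernels at dilations
1, 2, 3, concatenated along channels) -> a dual-branch attention module
(D-BA; channel attention and spatial attention applied in parallel, their
outputs fused) -> a final conv block with max-pool and batch-norm -> a
fully-connected classifier with dropout after its first layer.

Dilation enlarges the receptive field (span 2d+1 for a 3x3 kernel) without
adding parameters, so distant facial action units can be related at the
same cost as local texture.  Ablation variants:

* ``MSAC`` — receptive-field-matched standard convolutions (3x3/5x5/7x7)
  in place of the dilated branches; strictly more parameters.
* ``WO_DBA`` — attention module removed.
* ``WO_DBA_MSDC`` — attention removed and the three branches collapsed to
  a single standard 3x3 convolution.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "MSDACConfig", "ConvBlock", "MSDC", "ChannelAttention", "SpatialAttention",
    "DualBranchAttention", "MSDAC", "build_variant", "parameter_count",
    "VARIANTS",
]

parameter_count = nn.parameter_count


@dataclasses.dataclass(frozen=True)
class MSDACConfig:
    """Architecture widths; defaults suit 48x48 grayscale inputs."""

    stem_channels: tuple[int, int] = (32, 64)
    branch_channels: int = 64
    dilations: tuple[int, int, int] = (1, 2, 3)
    attention_reduction: int = 4
    final_channels: int = 64
    fc_hidden: int = 128
    classifier_dropout: float = 0.2
    n_classes: int = 2
    input_size: int = 48
    dba_fusion: str = "sum"  # "sum" | "average"

    def __post_init__(self):
        if self.dilations[0] != 1 or list(self.dilations) != sorted(set(self.dilations)):
            raise ValueError("dilations must be strictly increasing, starting at 1")
        if not 0.0 <= self.classifier_dropout < 1.0:
            raise ValueError("classifier_dropout must lie in [0,1)")
        if self.dba_fusion not in ("sum", "average"):
            raise ValueError("dba_fusion must be 'sum' or 'average'")


class ConvBlock(nn.Module):
    """convolution + batch-norm + ReLU + 2x2 max-pool."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator, pool: bool = True):
        super().__init__()
        self.conv = nn.Conv2d(in_channels, out_channels, 3, rng)
        self.bn = nn.BatchNorm2d(out_channels)
        self.pool = nn.MaxPool2d(2) if pool else None

    def forward(self, x: Tensor) -> Tensor:
        x = self.bn(self.conv(x)).relu()
        return self.pool(x) if self.pool is not None else x


class MSDC(nn.Module):
    """Parallel multi-scale branches concatenated along channels.

    With ``dilated=True`` each branch is a 3x3 convolution at dilation
    d in ``dilations`` (span 2d+1, padding d: spatial size preserved).
    With ``dilated=False`` (the MSAC variant) branch i uses a standard
    kernel of size 2d+1 — the same receptive field bought with (2d+1)^2/9
    times the weights.
    """

    def __init__(self, in_channels: int, branch_channels: int,
                 dilations: tuple[int, ...], rng: np.random.Generator,
                 dilated: bool = True):
        super().__init__()
        branches = []
        for d in dilations:
            if dilated:
                conv = nn.Conv2d(in_channels, branch_channels, 3, rng,
                                 dilation=d, padding=d)
            else:
                k = 2 * d + 1
                conv = nn.Conv2d(in_channels, branch_channels, k, rng,
                                 padding=(k - 1) // 2)
            branches.append(conv)
        self.branches = branches
        for i, b in enumerate(branches):
            setattr(self, f"branch{i}", b)
        self.max_span = max(b.span for b in branches)

    @property
    def out_channels(self) -> int:
        return len(self.branches) * self.branches[0].weight.shape[0]

    def forward(self, x: Tensor) -> Tensor:
        if min(x.shape[2], x.shape[3]) < self.max_span:
            raise ValueError(
                f"input {x.shape[2]}x{x.shape[3]} smaller than the largest "
                f"effective kernel span {self.max_span}")
        return nn.concatenate([b(x).relu() for b in self.branches], axis=1)


class ChannelAttention(nn.Module):
    """Squeeze-and-excitation style channel gate.

    Global average pooling gives one descriptor per channel; two FC layers
    (bottleneck of width channels/reduction) and a sigmoid yield a gate in
    (0,1) multiplied channel-wise into the input.
    """

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        super().__init__()
        if channels % reduction:
            raise ValueError(
                f"channels {channels} not divisible by reduction {reduction}")
        self.fc1 = nn.Linear(channels, channels // reduction, rng)
        self.fc2 = nn.Linear(channels // reduction, channels, rng)

    def gates(self, x: Tensor) -> Tensor:
        pooled = x.mean(axis=(2, 3))  # (N, C) spatial mean per channel
        return self.fc2(self.fc1(pooled).relu()).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        g = self.gates(x)
        return x * g.reshape(g.shape[0], g.shape[1], 1, 1)


class SpatialAttention(nn.Module):
    """Per-position gate: channel-mean map -> 1x1 conv -> sigmoid."""

    def __init__(self, rng: np.random.Generator):
        super().__init__()
        self.conv = nn.Conv2d(1, 1, 1, rng, padding=0)

    def gates(self, x: Tensor) -> Tensor:
        pooled = x.mean(axis=1, keepdims=True)  # (N, 1, H, W)
        return self.conv(pooled).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        return x * self.gates(x)


class DualBranchAttention(nn.Module):
    """Channel and spatial attention applied in parallel, outputs fused
    element-wise (sum by default, or average)."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator,
                 fusion: str = "sum"):
        super().__init__()
        self.channel = ChannelAttention(channels, reduction, rng)
        self.spatial = SpatialAttention(rng)
        self.fusion = fusion

    def forward(self, x: Tensor) -> Tensor:
        out = self.channel(x) + self.spatial(x)
        return out * 0.5 if self.fusion == "average" else out


VARIANTS = ("MSDAC", "MSAC", "WO_DBA", "WO_DBA_MSDC")


class MSDAC(nn.Module):
    """The full facial classifier; ablations controlled by flags."""

    def __init__(self, cfg: MSDACConfig = MSDACConfig(),
                 rng: np.random.Generator | None = None,
                 dilated: bool = True, use_dba: bool = True,
                 multi_scale: bool = True):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.cfg = cfg
        s1, s2 = cfg.stem_channels
        self.stem1 = ConvBlock(1, s1, rng)
        self.stem2 = ConvBlock(s1, s2, rng)
        if multi_scale:
            self.msdc = MSDC(s2, cfg.branch_channels, cfg.dilations, rng,
                             dilated=dilated)
            trunk_channels = self.msdc.out_channels
        else:
            self.msdc = None
            self.single = nn.Conv2d(s2, cfg.branch_channels, 3, rng)
            trunk_channels = cfg.branch_channels
        if use_dba:
            self.dba = DualBranchAttention(trunk_channels,
                                           cfg.attention_reduction, rng,
                                           fusion=cfg.dba_fusion)
        else:
            self.dba = None
        self.final_conv = nn.Conv2d(trunk_channels, cfg.final_channels, 3, rng)
        self.final_pool = nn.MaxPool2d(2)
        self.final_bn = nn.BatchNorm2d(cfg.final_channels)
        self.dropout = nn.Dropout(cfg.classifier_dropout, rng)
        # three 2x halvings of the spatial size (two stem pools + final pool)
        side = cfg.input_size // 8
        flat_dim = cfg.final_channels * side * side
        self.fc1 = nn.Linear(flat_dim, cfg.fc_hidden, rng)
        self.fc2 = nn.Linear(cfg.fc_hidden, cfg.n_classes, rng)

    def features(self, x: Tensor) -> Tensor:
        """Penultimate representation (input to the final FC layer)."""
        if not np.isfinite(x.data).all():
            raise ValueError("non-finite values in input images")
        h = self.stem2(self.stem1(x))
        h = self.msdc(h) if self.msdc is not None else self.single(h).relu()
        if self.dba is not None:
            h = self.dba(h)
        h = self.final_bn(self.final_pool(self.final_conv(h).relu()))
        flat = h.reshape(h.shape[0], -1)
        return self.dropout(self.fc1(flat).relu())

    def logits(self, x: Tensor) -> Tensor:
        return self.fc2(self.features(x))

    def forward(self, x: Tensor) -> Tensor:
        """Class probabilities for a batch of (N, 1, H, W) images."""
        return self.logits(x).softmax(axis=-1)


def build_variant(name: str, cfg: MSDACConfig = MSDACConfig(),
                  rng: np.random.Generator | None = None) -> MSDAC:
    """Construct the full model or one of its ablation variants by name."""
    if name == "MSDAC":
        return MSDAC(cfg, rng)
    if name == "MSAC":
        return MSDAC(cfg, rng, dilated=False)
    if name == "WO_DBA":
        return MSDAC(cfg, rng, use_dba=False)
    if name == "WO_DBA_MSDC":
        return MSDAC(cfg, rng, use_dba=False, multi_scale=False)
    raise ValueError(f"unknown variant {name!r}; valid: {', '.join(VARIANTS)}")
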