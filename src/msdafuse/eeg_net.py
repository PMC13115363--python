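"""EEG classifier over (6, 4, 8, 9) differential-entropy tensors.

Pipeline: a band-preserving 3x3 convolutional stem applied per time step,
spectral attention (the 4 band maps of a step as tokens, each a flattened
72-dim spatial vector), spatial attention (the 72 grid cells as tokens,
their 4-dim band profiles linearly embedded), a temporal weighting that
assigns each of the 6 steps a non-negative scalar (linear projection +
ReLU, normalised to sum to one when any weight is positive), then a
flatten to 1728 = 6*4*8*9, dropout 0.5, and a fully-connected softmax
layer.  Both attention stages are single-layer 4-head transformer
encoders with embedding dimension 72.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import nn
from .nn import Tensor

__all__ = ["EEGNetConfig", "SpectralAttention", "SpatialAttentionEEG",
           "TemporalWeighting", "EEGNet"]

STEPS, BANDS, ROWS, COLS = 6, 4, 8, 9
GRID = ROWS * COLS  # 72
FLAT = STEPS * BANDS * GRID  # 1728


@dataclasses.dataclass(frozen=True)
class EEGNetConfig:
    heads: int = 4
    embed_dim: int = 72
    encoder_layers: int = 1
    head_dropout: float = 0.5
    n_classes: int = 2

    def __post_init__(self):
        if self.embed_dim % self.heads:
            raise ValueError("embed_dim must be divisible by heads")


def _check_shape(x: Tensor) -> None:
    if x.ndim != 5 or x.shape[1:] != (STEPS, BANDS, ROWS, COLS):
        raise ValueError(
            f"expected (N, {STEPS}, {BANDS}, {ROWS}, {COLS}) tensors, "
            f"got {x.shape}")


class SpectralAttention(nn.Module):
    """Self-attention across the 4 frequency bands of each time step.

    Tokens: per (sample, step), the 4 bands, each represented by its
    flattened 8x9 spatial map (72 dims).  The per-head attention matrices
    (4 x 4) of the last forward pass are exposed on ``last_attention``.
    """

    def __init__(self, cfg: EEGNetConfig, rng: np.random.Generator):
        super().__init__()
        self.encoder = nn.TransformerEncoderLayer(cfg.embed_dim, cfg.heads, rng)

    @property
    def last_attention(self) -> np.ndarray | None:
        return self.encoder.attn.last_attention

    def forward(self, x: Tensor) -> Tensor:
        _check_shape(x)
        n = x.shape[0]
        tokens = x.reshape(n * STEPS, BANDS, GRID)
        out = self.encoder(tokens)
        return out.reshape(n, STEPS, BANDS, ROWS, COLS)


class SpatialAttentionEEG(nn.Module):
    """Self-attention across the 72 grid positions of each time step.

    Tokens: per (sample, step), the 72 cells, each a 4-dim band profile
    linearly embedded to 72 dims, encoded, then projected back to 4 dims so
    the (N, 6, 4, 8, 9) shape is restored.
    """

    def __init__(self, cfg: EEGNetConfig, rng: np.random.Generator):
        super().__init__()
        self.embed = nn.Linear(BANDS, cfg.embed_dim, rng)
        self.encoder = nn.TransformerEncoderLayer(cfg.embed_dim, cfg.heads, rng)
        self.unembed = nn.Linear(cfg.embed_dim, BANDS, rng)

    @property
    def last_attention(self) -> np.ndarray | None:
        return self.encoder.attn.last_attention

    def forward(self, x: Tensor) -> Tensor:
        _check_shape(x)
        n = x.shape[0]
        # (N*6, 72, 4) band profiles per grid cell
        tokens = x.reshape(n * STEPS, BANDS, GRID).transpose(0, 2, 1)
        out = self.unembed(self.encoder(self.embed(tokens)))
        return out.transpose(0, 2, 1).reshape(n, STEPS, BANDS, ROWS, COLS)


class TemporalWeighting(nn.Module):
    """One non-negative scalar weight per time step.

    Each step's flattened representation passes a linear projection and a
    ReLU; the resulting weights are normalised to sum to one over the six
    steps (a step whose weight is zero contributes a zero block; if every
    weight is zero the whole representation is zeroed).  Steps are kept and
    flattened downstream rather than summed, preserving the 1728-dim
    classifier input.
    """

    def __init__(self, rng: np.random.Generator):
        super().__init__()
        self.proj = nn.Linear(BANDS * GRID, 1, rng)

    def weights(self, x: Tensor) -> Tensor:
        n = x.shape[0]
        per_step = x.reshape(n, STEPS, BANDS * GRID)
        w = self.proj(per_step).relu().reshape(n, STEPS)
        total = w.sum(axis=1, keepdims=True)
        return w / (total + 1e-12)

    def forward(self, x: Tensor) -> Tensor:
        _check_shape(x)
        w = self.weights(x)
        return x * w.reshape(x.shape[0], STEPS, 1, 1, 1)


class EEGNet(nn.Module):
    """Full EEG branch classifier."""

    def __init__(self, cfg: EEGNetConfig = EEGNetConfig(),
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.cfg = cfg
        self.stem = nn.Conv2d(BANDS, BANDS, 3, rng)
        self.spectral = SpectralAttention(cfg, rng)
        self.spatial = SpatialAttentionEEG(cfg, rng)
        self.temporal = TemporalWeighting(rng)
        self.dropout = nn.Dropout(cfg.head_dropout, rng)
        self.fc = nn.Linear(FLAT, cfg.n_classes, rng)

    def features(self, x: Tensor) -> Tensor:
        """Penultimate 1728-dim representation (before dropout and FC)."""
        _check_shape(x)
        n = x.shape[0]
        h = self.stem(x.reshape(n * STEPS, BANDS, ROWS, COLS)).relu()
        h = h.reshape(n, STEPS, BANDS, ROWS, COLS)
        h = self.spectral(h)
        h = self.spatial(h)
        h = self.temporal(h)
        return h.reshape(n, FLAT)

    def logits(self, x: Tensor) -> Tensor:
        return self.fc(self.dropout(self.features(x)))

    def forward(self, x: Tensor) -> Tensor:
        return self.logits(x).softmax(axis=-1)
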