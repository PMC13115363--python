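"""Decision-level fusion of two modality classifiers.

Three strategies over per-sample class-probability pairs (X_E, X_F):

* **Self-learning weight fusion** — the concatenated probability rows are
  expanded through four GELU fully-connected layers to width L*E, reshaped
  into an L-token sequence, passed through multi-head self-attention that
  adaptively weights the cross-modal evidence, and mapped by a final
  softmax layer back to class probabilities.
* **Fixed-weight fusion** — the convex combination k*X_E + (1-k)*X_F with a
  single scalar weight, typically chosen by validation grid search.
* **Feature-level fusion** — concatenates the two branches' penultimate
  feature vectors and trains a fresh two-layer classifier head (baseline).

Modality dropout — replacing one modality's row with the uniform
distribution during training — makes the learned fusion robust to a
missing or uninformative modality.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "DecisionPair", "FusionConfig", "fuse_fixed", "concat_decisions",
    "modality_dropout", "MLPExpand", "SelfLearningFusion",
    "FeatureLevelFusionHead", "grid_search_fixed_weight",
]

_SIMPLEX_ATOL = 1e-6


@dataclasses.dataclass
class DecisionPair:
    """Per-sample class-probability outputs of the two modality branches."""

    p_eeg: np.ndarray   # (N, D)
    p_face: np.ndarray  # (N, D)
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.p_eeg = np.asarray(self.p_eeg, dtype=np.float64)
        self.p_face = np.asarray(self.p_face, dtype=np.float64)
        if self.p_eeg.shape != self.p_face.shape:
            raise ValueError("modality probability matrices differ in shape")
        for name, p in (("p_eeg", self.p_eeg), ("p_face", self.p_face)):
            if (p < -_SIMPLEX_ATOL).any():
                raise ValueError(f"{name} contains negative probabilities")
            if not np.allclose(p.sum(axis=1), 1.0, atol=_SIMPLEX_ATOL):
                raise ValueError(f"{name} rows must sum to 1")
        if self.labels is not None and len(self.labels) != len(self.p_eeg):
            raise ValueError("labels length mismatch")

    @property
    def n(self) -> int:
        return self.p_eeg.shape[0]

    @property
    def n_classes(self) -> int:
        return self.p_eeg.shape[1]


@dataclasses.dataclass(frozen=True)
class FusionConfig:
    """Architecture constants of the self-learning weight module.

    ``hidden_widths`` are the four expansion-layer widths H1..H4 (the last
    must equal L*E); the L*E activation is reshaped into L tokens of E
    dimensions for the attention stage with ``heads`` heads of size
    d_k = E / heads.
    """

    hidden_widths: tuple[int, int, int, int] = (16, 32, 64, 64)
    seq_len: int = 8
    embed: int = 8
    heads: int = 4
    modality_dropout_p: float = 0.1

    def __post_init__(self):
        if self.hidden_widths[3] != self.seq_len * self.embed:
            raise ValueError("hidden_widths[3] must equal seq_len * embed")
        if self.embed % self.heads:
            raise ValueError("embed must be divisible by heads")
        if any(a > b for a, b in zip(self.hidden_widths, self.hidden_widths[1:])):
            raise ValueError("hidden widths must be non-decreasing")

    @property
    def d_k(self) -> int:
        return self.embed // self.heads


def fuse_fixed(pair: DecisionPair, k: float) -> np.ndarray:
    """Convex combination k*X_E + (1-k)*X_F; rows stay on the simplex."""
    if not 0.0 <= k <= 1.0:
        raise ValueError(f"fixed weight k={k} outside [0,1]")
    return k * pair.p_eeg + (1.0 - k) * pair.p_face


def concat_decisions(pair: DecisionPair) -> np.ndarray:
    """Column-wise concatenation (X_E, X_F) -> (N, 2D), EEG columns first."""
    return np.concatenate([pair.p_eeg, pair.p_face], axis=1)


def modality_dropout(pair: DecisionPair, p: float,
                     rng: np.random.Generator) -> DecisionPair:
    """Randomly replace a modality's row by the uniform distribution.

    Per sample, each modality is dropped with probability exactly ``p``
    and never both for the same sample.  Those two requirements are only
    jointly satisfiable for p <= 0.5 (expected drops per sample is 2p),
    so the drops are drawn mutually exclusively: one uniform draw selects
    "drop EEG" with probability p, "drop face" with probability p, or
    "keep both" otherwise.  p outside [0, 0.5] is rejected (in particular
    p = 1, which would always violate the never-both rule).
    """
    if not 0.0 <= p <= 0.5:
        raise ValueError(
            f"modality dropout probability {p} must lie in [0,1) and cannot "
            f"exceed 0.5 under the exact-rate, never-both-dropped contract")
    if p == 0.0:
        return pair
    n, d = pair.p_eeg.shape
    u = rng.random(n)
    drop_e = u < p
    drop_f = (u >= p) & (u < 2 * p)
    uniform = np.full(d, 1.0 / d)
    p_eeg = pair.p_eeg.copy()
    p_face = pair.p_face.copy()
    p_eeg[drop_e] = uniform
    p_face[drop_f] = uniform
    return DecisionPair(p_eeg=p_eeg, p_face=p_face, labels=pair.labels)


class MLPExpand(nn.Module):
    """Four affine+GELU layers expanding 2D inputs to width L*E."""

    def __init__(self, in_dim: int, cfg: FusionConfig, rng: np.random.Generator):
        super().__init__()
        widths = (in_dim,) + tuple(cfg.hidden_widths)
        self.blocks = nn.Sequential(*[
            nn.Sequential(nn.Linear(widths[i], widths[i + 1], rng), nn.GELU())
            for i in range(4)])

    def forward(self, x: Tensor) -> Tensor:
        return self.blocks(x)


class SelfLearningFusion(nn.Module):
    """Self-learning weight module: concat -> MLP expand -> reshape to an
    L-token sequence -> multi-head self-attention -> flatten -> softmax."""

    def __init__(self, n_classes: int = 2, cfg: FusionConfig = FusionConfig(),
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.cfg = cfg
        self.n_classes = n_classes
        self.expand = MLPExpand(2 * n_classes, cfg, rng)
        self.attn = nn.MultiHeadSelfAttention(cfg.embed, cfg.heads, rng)
        self.out = nn.Linear(cfg.seq_len * cfg.embed, n_classes, rng)

    def logits(self, x: Tensor) -> Tensor:
        cfg = self.cfg
        h = self.expand(x)
        seq = h.reshape(-1, cfg.seq_len, cfg.embed)
        attn = self.attn(seq)
        flat = attn.reshape(-1, cfg.seq_len * cfg.embed)
        return self.out(flat)

    def forward(self, x: Tensor) -> Tensor:
        return self.logits(x).softmax(axis=-1)

    def predict_proba(self, pair: DecisionPair) -> np.ndarray:
        self.eval()
        with nn.no_grad():
            return self.forward(Tensor(concat_decisions(pair))).data


def fuse_self_learning(pair: DecisionPair, model: SelfLearningFusion) -> np.ndarray:
    """Apply a (trained) self-learning fusion model to a decision pair."""
    return model.predict_proba(pair)


class FeatureLevelFusionHead(nn.Module):
    """Two-layer classifier over concatenated penultimate branch features."""

    def __init__(self, eeg_dim: int, face_dim: int, n_classes: int = 2,
                 hidden: int = 64, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.fc1 = nn.Linear(eeg_dim + face_dim, hidden, rng)
        self.fc2 = nn.Linear(hidden, n_classes, rng)

    def logits(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())

    def forward(self, x: Tensor) -> Tensor:
        return self.logits(x).softmax(axis=-1)


def grid_search_fixed_weight(train_pair: DecisionPair,
                             grid: np.ndarray | None = None) -> float:
    """Pick the fixed weight k maximising accuracy on validation decisions."""
    if train_pair.labels is None:
        raise ValueError("labelled decisions required for the grid search")
    grid = np.round(np.arange(0.0, 1.01, 0.1), 10) if grid is None else grid
    best_k, best_acc = 0.5, -1.0
    for k in grid:
        fused = fuse_fixed(train_pair, float(k))
        acc = float((fused.argmax(axis=1) == train_pair.labels).mean())
        if acc > best_acc:
            best_k, best_acc = float(k), acc
    return best_k
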