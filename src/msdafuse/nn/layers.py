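"""Neural-network building blocks over the autodiff engine.

Modules follow the familiar forward/parameters/train-eval protocol. Weight
initialisation is He/Glorot as appropriate, drawn from a numpy Generator so
whole models are reproducible from a single seed.
"""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor, concatenate

__all__ = [
    "Module", "Sequential", "Linear", "Conv2d", "MaxPool2d", "BatchNorm2d",
    "LayerNorm", "Dropout", "ReLU", "GELU", "Sigmoid", "Flatten",
    "MultiHeadSelfAttention", "TransformerEncoderLayer",
    "cross_entropy", "parameter_count",
]


class Module:
    """Base class: tracks parameters, submodules and train/eval mode."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def modules(self) -> list["Module"]:
        out = [self]
        for m in self._modules.values():
            out.extend(m.modules())
        return out

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + k: v.data.copy() for k, v in self._params.items()}
        for name, m in self._modules.items():
            out.update(m.state_dict(prefix + name + "."))
        for extra in getattr(self, "_buffers", ()):
            out[prefix + extra] = getattr(self, extra).copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for k, v in self._params.items():
            v.data = state[prefix + k].copy()
        for extra in getattr(self, "_buffers", ()):
            setattr(self, extra, state[prefix + extra].copy())
        for name, m in self._modules.items():
            m.load_state_dict(state, prefix + name + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def parameter_count(model: Module) -> int:
    """Total number of trainable scalars in a model."""
    return int(sum(p.data.size for p in model.parameters()))


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"layer{i}", layer)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        bound = math.sqrt(6.0 / (in_features + out_features))
        self.weight = Tensor(rng.uniform(-bound, bound, (in_features, out_features)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class GELU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.gelu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Flatten(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.reshape(x.shape[0], -1)


class Dropout(Module):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0,1), got {p}")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class Conv2d(Module):
    """2-D convolution with optional dilation, stride 1, zero padding.

    The effective span of a k x k kernel at dilation d is (k-1)*d + 1; with
    padding d (for k=3) the spatial size is preserved at every dilation, which
    is what lets parallel multi-dilation branches concatenate cleanly.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, dilation: int = 1,
                 padding: int | None = None):
        super().__init__()
        self.kernel_size = kernel_size
        self.dilation = dilation
        self.padding = padding if padding is not None else dilation * (kernel_size - 1) // 2
        fan_in = in_channels * kernel_size * kernel_size
        bound = math.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, bound, (out_channels, in_channels, kernel_size, kernel_size)),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)

    @property
    def span(self) -> int:
        return (self.kernel_size - 1) * self.dilation + 1

    def forward(self, x: Tensor) -> Tensor:
        k, d, p = self.kernel_size, self.dilation, self.padding
        w, b = self.weight, self.bias
        n, c, h, wd = x.shape
        ho = h + 2 * p - (k - 1) * d
        wo = wd + 2 * p - (k - 1) * d
        if ho <= 0 or wo <= 0:
            raise ValueError(
                f"input {h}x{wd} smaller than effective kernel span {self.span}")
        xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
        # gather k*k dilated taps: cols[n, c, i, j, ho, wo]
        cols = np.empty((n, c, k, k, ho, wo))
        for i in range(k):
            for j in range(k):
                cols[:, :, i, j] = xp[:, :, i * d:i * d + ho, j * d:j * d + wo]
        out = np.tensordot(cols, w.data, axes=([1, 2, 3], [1, 2, 3]))
        out = out.transpose(0, 3, 1, 2) + b.data[None, :, None, None]

        def backward(g):
            # g: (n, oc, ho, wo)
            if w.requires_grad:
                gw = np.tensordot(g, cols, axes=([0, 2, 3], [0, 4, 5]))
                w._accumulate(gw)
            if b.requires_grad:
                b._accumulate(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gcols = np.tensordot(g, w.data, axes=([1], [0]))  # n,ho,wo,c,k,k
                gxp = np.zeros_like(xp)
                for i in range(k):
                    for j in range(k):
                        gxp[:, :, i * d:i * d + ho, j * d:j * d + wo] += \
                            gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                gx = gxp[:, :, p:p + h, p:p + wd] if p else gxp
                x._accumulate(gx)

        return Tensor._make(out, (x, w, b), backward)


class MaxPool2d(Module):
    """Non-overlapping max pooling (kernel == stride); trailing rows/cols
    that do not fill a window are dropped."""

    def __init__(self, kernel_size: int = 2):
        super().__init__()
        self.k = kernel_size

    def forward(self, x: Tensor) -> Tensor:
        k = self.k
        n, c, h, w = x.shape
        ho, wo = h // k, w // k
        xv = x.data[:, :, :ho * k, :wo * k].reshape(n, c, ho, k, wo, k)
        xv = xv.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, k * k)
        arg = xv.argmax(axis=-1)
        out = np.take_along_axis(xv, arg[..., None], axis=-1)[..., 0]

        def backward(g):
            if not x.requires_grad:
                return
            gwin = np.zeros((n, c, ho, wo, k * k))
            np.put_along_axis(gwin, arg[..., None], g[..., None], axis=-1)
            gwin = gwin.reshape(n, c, ho, wo, k, k).transpose(0, 1, 2, 4, 3, 5)
            gx = np.zeros_like(x.data)
            gx[:, :, :ho * k, :wo * k] = gwin.reshape(n, c, ho * k, wo * k)
            x._accumulate(gx)

        return Tensor._make(out, (x,), backward)


class BatchNorm2d(Module):
    _buffers = ("running_mean", "running_var")

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: Tensor) -> Tensor:
        gamma, beta, eps = self.gamma, self.beta, self.eps
        axes = (0, 2, 3)
        if self.training:
            mu = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu
            self.running_var = (1 - m) * self.running_var + m * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x.data - mu[None, :, None, None]) * inv[None, :, None, None]
        out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
        training = self.training
        nspatial = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

        def backward(g):
            if gamma.requires_grad:
                gamma._accumulate((g * xhat).sum(axis=axes))
            if beta.requires_grad:
                beta._accumulate(g.sum(axis=axes))
            if x.requires_grad:
                gxhat = g * gamma.data[None, :, None, None]
                if training:
                    # full batch-norm backward through mu and var
                    term = (gxhat
                            - gxhat.mean(axis=axes, keepdims=True)
                            - xhat * (gxhat * xhat).sum(axis=axes, keepdims=True) / nspatial)
                    x._accumulate(term * inv[None, :, None, None])
                else:
                    x._accumulate(gxhat * inv[None, :, None, None])

        return Tensor._make(out, (x, gamma, beta), backward)


class LayerNorm(Module):
    """Normalisation over the last axis."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        gamma, beta = self.gamma, self.beta
        mu = x.data.mean(axis=-1, keepdims=True)
        var = x.data.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu) * inv
        out = gamma.data * xhat + beta.data
        d = x.shape[-1]

        def backward(g):
            if gamma.requires_grad:
                gamma._accumulate((g * xhat).reshape(-1, d).sum(axis=0))
            if beta.requires_grad:
                beta._accumulate(g.reshape(-1, d).sum(axis=0))
            if x.requires_grad:
                gxhat = g * gamma.data
                term = (gxhat
                        - gxhat.mean(axis=-1, keepdims=True)
                        - xhat * (gxhat * xhat).mean(axis=-1, keepdims=True))
                x._accumulate(term * inv)

        return Tensor._make(out, (x, gamma, beta), backward)


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention with n parallel heads.

    Per head h: Q_h = X S_h^Q, K_h = X S_h^K, V_h = X S_h^V, then
    softmax(Q_h K_h^T / sqrt(d_k)) V_h; head outputs are concatenated and
    mixed by an output projection W^O.  The last computed attention maps are
    kept on `last_attention` (shape [batch, heads, L, L]) for inspection.
    """

    def __init__(self, embed_dim: int, num_heads: int, rng: np.random.Generator):
        super().__init__()
        if embed_dim % num_heads:
            raise ValueError(f"embed_dim {embed_dim} not divisible by heads {num_heads}")
        self.embed_dim = embed_dim
        self.num_heads = num_heads
        self.d_k = embed_dim // num_heads
        self.q_proj = Linear(embed_dim, embed_dim, rng)
        self.k_proj = Linear(embed_dim, embed_dim, rng)
        self.v_proj = Linear(embed_dim, embed_dim, rng)
        self.out_proj = Linear(embed_dim, embed_dim, rng)
        self.last_attention: np.ndarray | None = None

    def _split(self, x: Tensor, n: int, L: int) -> Tensor:
        # (N, L, E) -> (N, heads, L, d_k)
        return x.reshape(n, L, self.num_heads, self.d_k).transpose(0, 2, 1, 3)

    def forward(self, x: Tensor) -> Tensor:
        n, L, e = x.shape
        q = self._split(self.q_proj(x), n, L)
        k = self._split(self.k_proj(x), n, L)
        v = self._split(self.v_proj(x), n, L)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(self.d_k))
        attn = scores.softmax(axis=-1)
        self.last_attention = attn.data
        ctx = attn @ v  # (N, heads, L, d_k)
        ctx = ctx.transpose(0, 2, 1, 3).reshape(n, L, e)
        return self.out_proj(ctx)


class TransformerEncoderLayer(Module):
    """Post-norm encoder block: MHSA + residual + LN, FFN + residual + LN."""

    def __init__(self, embed_dim: int, num_heads: int, rng: np.random.Generator,
                 ffn_dim: int | None = None):
        super().__init__()
        ffn_dim = ffn_dim or 2 * embed_dim
        self.attn = MultiHeadSelfAttention(embed_dim, num_heads, rng)
        self.norm1 = LayerNorm(embed_dim)
        self.ffn1 = Linear(embed_dim, ffn_dim, rng)
        self.ffn2 = Linear(ffn_dim, embed_dim, rng)
        self.norm2 = LayerNorm(embed_dim)

    def forward(self, x: Tensor) -> Tensor:
        x = self.norm1(x + self.attn(x))
        return self.norm2(x + self.ffn2(self.ffn1(x).relu()))


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer labels under softmax(logits)."""
    labels = np.asarray(labels, dtype=np.intp)
    logp = logits.log_softmax(axis=-1)
    n = logits.shape[0]
    picked = logp[np.arange(n), labels]
    return -picked.mean()
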