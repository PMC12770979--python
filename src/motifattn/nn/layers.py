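"""Neural-network layers built on the autograd engine.

All parameters are float64 numpy arrays wrapped in :class:`Tensor`; layers
expose a ``parameters()`` list for the optimizer and are deterministic given
the ``numpy.random.Generator`` used at construction.
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor, cat, conv1d

__all__ = [
    "Dense", "Conv1d", "BatchNorm1d", "LayerNorm", "MultiHeadSelfAttention",
    "BiLSTM", "sinusoidal_encoding",
]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape: tuple[int, ...]) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params


class Dense(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w = Tensor(_glorot(rng, d_in, d_out, (d_in, d_out)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.matmul(self.w) + self.b


class Conv1d(Module):
    """Same-padding 1-D convolution; weight (out, in, k)."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, dilation: int = 1,
                 trainable: bool = True):
        fan_in, fan_out = c_in * kernel, c_out * kernel
        self.w = Tensor(_glorot(rng, fan_in, fan_out, (c_out, c_in, kernel)),
                        requires_grad=trainable)
        self.b = Tensor(np.zeros(c_out), requires_grad=trainable)
        self.dilation = dilation

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.w, self.b, dilation=self.dilation)


class BatchNorm1d(Module):
    """Batch normalization over (B, C, L) activations (per-channel).

    Uses batch statistics while ``training`` is True and running averages
    otherwise; the flag is flipped by the owning model.
    """

    def __init__(self, channels: int, momentum: float = 0.1,
                 eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mean = x.data.mean(axis=(0, 2))
            var = x.data.var(axis=(0, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            mu = x.mean(axis=(0, 2), keepdims=True)
            centered = x - mu
            v = (centered * centered).mean(axis=(0, 2), keepdims=True)
            norm = centered * (v + self.eps) ** -0.5
        else:
            mu = self.running_mean[None, :, None]
            sd = np.sqrt(self.running_var + self.eps)[None, :, None]
            norm = (x - Tensor(mu)) * Tensor(1.0 / sd)
        return norm * self.gamma.reshape(1, -1, 1) \
            + self.beta.reshape(1, -1, 1)


class LayerNorm(Module):
    """Layer normalization over the last axis."""

    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered * (var + self.eps) ** -0.5 * self.gamma + self.beta


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention with h heads of width d_k.

    Query/key/value projections are learned jointly as (d_in, h*d_k)
    matrices; the per-head attention matrices are returned alongside the
    concatenated context so they can be regularized, inspected, or replaced.
    """

    def __init__(self, d_in: int, n_heads: int, d_k: int,
                 rng: np.random.Generator, init_gain: float = 1.0):
        self.n_heads = n_heads
        self.d_k = d_k
        d_proj = n_heads * d_k
        self.wq = Tensor(init_gain * _glorot(rng, d_in, d_proj,
                                             (d_in, d_proj)),
                         requires_grad=True)
        self.wk = Tensor(init_gain * _glorot(rng, d_in, d_proj,
                                             (d_in, d_proj)),
                         requires_grad=True)
        self.wv = Tensor(_glorot(rng, d_in, d_proj, (d_in, d_proj)),
                         requires_grad=True)

    def _split(self, t: Tensor, B: int, n: int) -> Tensor:
        # (B, n, h*dk) -> (B, h, n, dk)
        return t.reshape(B, n, self.n_heads, self.d_k).transpose(0, 2, 1, 3)

    def __call__(self, x: Tensor, attn_override: Tensor | None = None
                 ) -> tuple[Tensor, Tensor]:
        """Returns (context (B, n, h*dk), attention (B, h, n, n)).

        ``attn_override`` replaces the computed attention matrices (used for
        attribution, where gradients with respect to the attention values
        are needed at scaled-down attention inputs).
        """
        B, n, _ = x.shape
        v = self._split(x.matmul(self.wv), B, n)
        if attn_override is not None:
            attn = attn_override
        else:
            q = self._split(x.matmul(self.wq), B, n)
            k = self._split(x.matmul(self.wk), B, n)
            scores = q.matmul(k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(self.d_k))
            attn = scores.softmax(axis=-1)
        z = attn.matmul(v)  # (B, h, n, dk)
        z = z.transpose(0, 2, 1, 3).reshape(B, n, self.n_heads * self.d_k)
        return z, attn


class BiLSTM(Module):
    """Single-layer bidirectional LSTM over (B, n, d) inputs.

    Gate order inside the packed weight matrices is input, forget, cell,
    output; forget-gate bias starts at 1 to ease gradient flow early on.
    """

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        self.params_fwd = self._direction_params(d_in, hidden, rng)
        self.params_bwd = self._direction_params(d_in, hidden, rng)

    def _direction_params(self, d_in, hidden, rng):
        wx = Tensor(_glorot(rng, d_in, 4 * hidden, (d_in, 4 * hidden)),
                    requires_grad=True)
        wh = Tensor(_glorot(rng, hidden, 4 * hidden, (hidden, 4 * hidden)),
                    requires_grad=True)
        b = np.zeros(4 * hidden)
        b[hidden:2 * hidden] = 1.0
        return [wx, wh, Tensor(b, requires_grad=True)]

    def parameters(self) -> list[Tensor]:
        return list(self.params_fwd) + list(self.params_bwd)

    def __call__(self, x: Tensor) -> Tensor:
        from .autograd import lstm_seq

        wx_f, wh_f, b_f = self.params_fwd
        wx_b, wh_b, b_b = self.params_bwd
        fwd = lstm_seq(x.matmul(wx_f), wh_f, b_f, reverse=False)
        bwd = lstm_seq(x.matmul(wx_b), wh_b, b_b, reverse=True)
        return cat([fwd, bwd], axis=2)


def sinusoidal_encoding(n: int, d: int) -> np.ndarray:
    """Fixed sine/cosine positional encoding, (n, d)."""
    pos = np.arange(n)[:, None]
    dim = np.arange(d)[None, :]
    angle = pos / np.power(10000.0, (2 * (dim // 2)) / d)
    enc = np.where(dim % 2 == 0, np.sin(angle), np.cos(angle))
    return enc
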