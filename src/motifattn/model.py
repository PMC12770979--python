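"""Sequence classifiers built around an interpretable self-attention layer.

Both architectures share the same front end: a 1D convolution over one-hot
DNA (the motif scanner), ReLU, and a small max-pool, followed by multi-head
scaled dot-product self-attention whose row-stochastic maps A^(k) are the
object of interpretation.  The *basic* model feeds the attention output
directly to fully-connected layers; the *deep* model appends residual dual
linear/non-linear convolution sub-blocks and dilated residual convolutions
before averaging along the sequence.

The training loss is ``classification + λ · entropy`` where the entropy term
is the mean Shannon row entropy of the attention maps summed over heads —
driving λ up pushes the maps toward sparse, near-one-hot rows, which is what
makes them readable.
"""

from __future__ import annotations

import math
import pickle
from dataclasses import dataclass, asdict

import numpy as np

from .motifs import MotifLibrary
from .nn import (BatchNorm1d, BiLSTM, Conv1d, Dense, LayerNorm,
                 MultiHeadSelfAttention, Tensor, bce_with_logits, maxpool1d,
                 no_grad, sinusoidal_encoding)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def one_hot_encode(sequence: str) -> np.ndarray:
    """One-hot encode a DNA string to a 4×L matrix (rows A,C,G,T); ``N``
    becomes an all-zero column."""
    L = len(sequence)
    out = np.zeros((4, L))
    for i, b in enumerate(sequence):
        if b == "N":
            continue
        try:
            out[_BASE_INDEX[b], i] = 1.0
        except KeyError:
            raise ValueError(f"invalid base {b!r} at position {i}") from None
    return out


def encode_batch(sequences: list[str]) -> np.ndarray:
    out = np.zeros((len(sequences), 4, len(sequences[0])))
    for k, s in enumerate(sequences):
        out[k] = one_hot_encode(s)
    return out


@dataclass
class ModelSpec:
    architecture: str = "basic"  # {basic, deep}
    n_filters: int = 32
    filter_length: int = 12
    pool_size: int = 4
    n_heads: int = 4
    head_dim: int = 8
    fc_hidden: int = 64
    use_batchnorm: bool = True
    attn_init_gain: float = 1.0
    use_rnn: bool = False
    rnn_hidden: int = 32
    use_positional_encoding: bool = False
    entropy_lambda: float = 0.0
    n_outputs: int = 1
    task: str = "binary"  # {binary, multilabel}
    # deep-architecture block (configurable; used when architecture="deep")
    n_dual_blocks: int = 2
    block_channels: int | None = None  # default: attention output width
    dilations: tuple[int, ...] = (2, 4, 8)
    # pre-loaded first-layer filters
    preloaded: MotifLibrary | None = None
    preloaded_trainable: bool = False

    def __post_init__(self):
        if self.architecture not in ("basic", "deep"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.pool_size > 4 or self.pool_size < 1:
            raise ValueError("pool_size must be in 1..4")
        if self.entropy_lambda < 0:
            raise ValueError("entropy_lambda must be >= 0")
        if self.n_heads < 1:
            raise ValueError("n_heads must be >= 1")
        if self.task not in ("binary", "multilabel"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.preloaded is not None:
            self.n_filters = len(self.preloaded)
            too_long = [m.name for m in self.preloaded
                        if len(m) > self.filter_length]
            if too_long:
                raise ValueError(
                    f"pre-loaded motifs longer than filter_length "
                    f"{self.filter_length}: {too_long}")

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.preloaded is not None:
            d["preloaded"] = {
                "source": self.preloaded.source,
                "motifs": [(m.name, m.matrix.tolist(),
                            m.background.tolist())
                           for m in self.preloaded]}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        from .motifs import PWM
        d = dict(d)
        if d.get("preloaded") is not None:
            p = d["preloaded"]
            d["preloaded"] = MotifLibrary(
                [PWM(n, np.array(m), np.array(b))
                 for n, m, b in p["motifs"]], source=p["source"])
        if "dilations" in d:
            d["dilations"] = tuple(d["dilations"])
        return cls(**d)


@dataclass
class ForwardOutput:
    """Everything interpretation needs from one forward pass."""

    predictions: np.ndarray          # probabilities, (B, n_outputs)
    logits: np.ndarray               # (B, n_outputs)
    attention: np.ndarray            # (B, h, n, n), rows sum to 1
    conv_activations: np.ndarray     # pooled ReLU conv output, (B, F, n)
    pooled_positions: list[tuple[int, int]]  # pooled idx -> seq window


def entropy_loss(maps) -> float:
    """Attention entropy: −Σ_heads (1/n) Σ_rows Σ_cols A log A (natural
    log, 0·log 0 = 0), averaged over the batch when given 4-D input.

    Accepts (h, n, n) or (B, h, n, n) arrays.  Ranges over [0, h·ln n].
    """
    a = np.asarray(maps, dtype=np.float64)
    if np.any(a < 0):
        raise ValueError("attention maps must be non-negative")
    if a.ndim == 3:
        a = a[None]
    n = a.shape[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(a > 0, a * np.log(np.where(a > 0, a, 1.0)), 0.0)
    per_head = -plogp.sum(axis=(-1, -2)) / n  # (B, h)
    return float(per_head.sum(axis=1).mean())


def _entropy_term(attn: Tensor) -> Tensor:
    n = attn.shape[-1]
    per_head = attn.xlogx().sum(axis=(-1, -2)) * (-1.0 / n)  # (B, h)
    return per_head.sum(axis=1).mean()


def total_loss(logits: Tensor, labels: np.ndarray, attn: Tensor,
               lam: float) -> Tensor:
    """Classification loss (mean binary cross-entropy; for multilabel the
    mean over labels) plus λ times the attention-entropy term."""
    labels = np.asarray(labels, dtype=np.float64)
    if labels.ndim == 1:
        labels = labels[:, None]
    if labels.shape != logits.shape:
        raise ValueError(
            f"label shape {labels.shape} != prediction shape {logits.shape}")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    loss = bce_with_logits(logits, labels)
    if lam > 0:
        loss = loss + lam * _entropy_term(attn)
    return loss


def self_attention(x: np.ndarray, wq: np.ndarray, wk: np.ndarray,
                   wv: np.ndarray, n_heads: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Functional multi-head attention on a single n×d matrix.

    Returns (attention (h, n, n), context (n, h·d_k)).  Weights are
    (d, h·d_k) matrices shared across positions.
    """
    n, d = x.shape
    d_proj = wq.shape[1]
    if wq.shape[0] != d or wk.shape != wq.shape or wv.shape != wq.shape:
        raise ValueError("weight shapes inconsistent with input")
    if d_proj % n_heads:
        raise ValueError("projection width must divide into heads")
    dk = d_proj // n_heads

    def split(m):
        return (x @ m).reshape(n, n_heads, dk).transpose(1, 0, 2)

    q, k, v = split(wq), split(wk), split(wv)
    scores = q @ k.transpose(0, 2, 1) / math.sqrt(dk)
    scores -= scores.max(axis=-1, keepdims=True)
    e = np.exp(scores)
    attn = e / e.sum(axis=-1, keepdims=True)
    z = (attn @ v).transpose(1, 0, 2).reshape(n, d_proj)
    return attn, z


class SequenceModel:
    """Built network; use :func:`build_model` rather than instantiating."""

    def __init__(self, spec: ModelSpec, seq_length: int, seed: int = 0):
        self.spec = spec
        self.seq_length = seq_length
        rng = np.random.default_rng(seed)
        F, k = spec.n_filters, spec.filter_length

        self.conv = Conv1d(4, F, k, rng,
                           trainable=spec.preloaded is None
                           or spec.preloaded_trainable)
        if spec.preloaded is not None:
            self.conv.w.data = self._preloaded_kernels(spec)
            self.conv.b.data[:] = 0.0

        # pre-loaded filters keep raw PSSM-score activations (no BN), so the
        # half-max-PSSM activity rule stays meaningful downstream
        self.bn = (BatchNorm1d(F) if spec.use_batchnorm
                   and spec.preloaded is None else None)
        self.training = False
        self.n_pooled = seq_length // spec.pool_size
        d_attn = F
        self.rnn = None
        if spec.use_rnn:
            self.rnn = BiLSTM(F, spec.rnn_hidden, rng)
            d_attn = 2 * spec.rnn_hidden
        self.posenc = (sinusoidal_encoding(self.n_pooled, d_attn)[None]
                       if spec.use_positional_encoding else None)
        # the attention input must be on a unit scale for the softmax to
        # leave the uniform regime quickly; the conv path gets this from
        # batch norm, so layer norm is added where that is not the case
        # (LSTM outputs, raw PSSM activations)
        self.attn_norm = (LayerNorm(d_attn)
                          if spec.use_rnn or self.bn is None else None)
        self.attention = MultiHeadSelfAttention(
            d_attn, spec.n_heads, spec.head_dim, rng,
            init_gain=spec.attn_init_gain)
        d_model = spec.n_heads * spec.head_dim

        # deep variant with entropy regularization routes a residual copy of
        # the conv features around the attention layer to protect accuracy
        self.attn_residual = (spec.architecture == "deep"
                              and spec.entropy_lambda > 0)
        self.res_proj = None
        if self.attn_residual and d_attn != d_model:
            self.res_proj = Dense(d_attn, d_model, rng)

        if spec.architecture == "deep":
            C = spec.block_channels or d_model
            self.in_proj = Dense(d_model, C, rng) if C != d_model else None
            self.dual_blocks = []
            for _ in range(spec.n_dual_blocks):
                self.dual_blocks.append(
                    (Conv1d(C, C, 3, rng), Conv1d(C, C, 3, rng)))
            self.dilated = [Conv1d(C, C, 3, rng, dilation=d)
                            for d in spec.dilations]
            self.fc1 = Dense(C, spec.fc_hidden, rng)
        else:
            self.dual_blocks = []
            self.dilated = []
            self.in_proj = None
            self.fc1 = Dense(self.n_pooled * d_model, spec.fc_hidden, rng)
        self.fc2 = Dense(spec.fc_hidden, spec.n_outputs, rng)

    @staticmethod
    def _preloaded_kernels(spec: ModelSpec) -> np.ndarray:
        """First-layer kernels as log2(p / 0.25) PSSMs, zero-padded."""
        F, k = spec.n_filters, spec.filter_length
        w = np.zeros((F, 4, k))
        for f, m in enumerate(spec.preloaded):
            pssm = np.log2(np.maximum(m.matrix, 1e-3) / 0.25).T  # (4, L)
            off = (k - len(m)) // 2
            w[f, :, off:off + len(m)] = pssm
        return w

    # -- parameters --------------------------------------------------------
    def set_training(self, flag: bool) -> None:
        self.training = flag
        if self.bn is not None:
            self.bn.training = flag

    def parameters(self) -> list[Tensor]:
        params = self.conv.parameters()
        if self.bn is not None:
            params += self.bn.parameters()
        if self.rnn is not None:
            params += self.rnn.parameters()
        if self.attn_norm is not None:
            params += self.attn_norm.parameters()
        params += self.attention.parameters()
        if self.res_proj is not None:
            params += self.res_proj.parameters()
        if self.in_proj is not None:
            params += self.in_proj.parameters()
        for lin, nonlin in self.dual_blocks:
            params += lin.parameters() + nonlin.parameters()
        for c in self.dilated:
            params += c.parameters()
        params += self.fc1.parameters() + self.fc2.parameters()
        return params

    def state_dict(self) -> list[np.ndarray]:
        state = [p.data.copy() for p in self.parameters()]
        if self.bn is not None:
            state += [self.bn.running_mean.copy(),
                      self.bn.running_var.copy()]
        return state

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if self.bn is not None:
            *param_state, rmean, rvar = state
            self.bn.running_mean[...] = rmean
            self.bn.running_var[...] = rvar
        else:
            param_state = state
        for p, s in zip(params, param_state, strict=True):
            p.data[...] = s

    def pooled_positions(self) -> list[tuple[int, int]]:
        """Sequence window [start, end) feeding each pooled position (the
        convolution is same-padded, so windows are clipped at the edges)."""
        p, k = self.spec.pool_size, self.spec.filter_length
        out = []
        for i in range(self.n_pooled):
            start = i * p - (k - 1) // 2
            end = i * p + p + (k - 1) - (k - 1) // 2
            out.append((max(0, start), min(self.seq_length, end)))
        return out

    # -- forward -----------------------------------------------------------
    def forward_graph(self, x: np.ndarray,
                      attn_override: Tensor | None = None
                      ) -> tuple[Tensor, Tensor, Tensor]:
        """Differentiable forward pass.

        Returns (logits, attention, pooled conv activations) as graph
        tensors; ``attn_override`` substitutes the attention matrices
        (used by attribution).
        """
        xt = Tensor(x)
        conv = self.conv(xt)
        if self.bn is not None:
            conv = self.bn(conv)
        conv = conv.relu()
        pooled = maxpool1d(conv, self.spec.pool_size)      # (B, F, n)
        feats = pooled.transpose(0, 2, 1)                  # (B, n, F)
        attn_in = self.rnn(feats) if self.rnn is not None else feats
        if self.attn_norm is not None:
            attn_in = self.attn_norm(attn_in)
        if self.posenc is not None:
            attn_in = attn_in + Tensor(self.posenc)
        z, attn = self.attention(attn_in, attn_override=attn_override)
        if self.attn_residual:
            res = attn_in
            if self.res_proj is not None:
                res = self.res_proj(res)
            z = z + res
        B, n, d_model = z.shape
        if self.spec.architecture == "deep":
            h = z
            if self.in_proj is not None:
                h = self.in_proj(h)
            h = h.transpose(0, 2, 1)  # (B, C, n)
            for lin, nonlin in self.dual_blocks:
                h = h + lin(h) + nonlin(h).relu()
            for c in self.dilated:
                h = h + c(h).relu()
            h = h.mean(axis=2)  # average along the sequence dimension
            hidden = self.fc1(h).relu()
        else:
            flat = z.relu().reshape(B, n * d_model)
            hidden = self.fc1(flat).relu()
        logits = self.fc2(hidden)
        return logits, attn, pooled

    def forward(self, sequences: list[str] | np.ndarray,
                batch_size: int = 256) -> ForwardOutput:
        """Inference-mode forward pass over raw sequences."""
        if isinstance(sequences, np.ndarray):
            x_all = sequences
        else:
            x_all = encode_batch(sequences)
        logits, attns, convs = [], [], []
        self.set_training(False)
        with no_grad():
            for lo in range(0, x_all.shape[0], batch_size):
                lg, at, cv = self.forward_graph(x_all[lo:lo + batch_size])
                logits.append(lg.data)
                attns.append(at.data)
                convs.append(cv.data)
        logits = np.concatenate(logits)
        probs = 0.5 * (np.tanh(0.5 * logits) + 1.0)
        return ForwardOutput(
            predictions=probs, logits=logits,
            attention=np.concatenate(attns),
            conv_activations=np.concatenate(convs),
            pooled_positions=self.pooled_positions())

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        payload = {"spec": self.spec.to_dict(),
                   "seq_length": self.seq_length,
                   "state": self.state_dict()}
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "SequenceModel":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        spec = ModelSpec.from_dict(payload["spec"])
        model = cls(spec, payload["seq_length"])
        model.load_state_dict(payload["state"])
        return model


def build_model(spec: ModelSpec, seq_length: int, seed: int = 0
                ) -> SequenceModel:
    """Construct a :class:`SequenceModel` for sequences of ``seq_length``."""
    return SequenceModel(spec, seq_length, seed=seed)
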