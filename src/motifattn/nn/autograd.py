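"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; calling :meth:`Tensor.backward` on a scalar result accumulates gradients
into every reachable leaf created with ``requires_grad=True``.  The op set is
deliberately small — exactly what a 1D-CNN + multi-head self-attention +
(optionally) bidirectional-LSTM sequence classifier needs — and every op is
vectorized, so the engine spends its time inside numpy, not Python.

Gradients with respect to *intermediate* quantities (in particular the
attention matrices) are obtained by feeding them back into the graph as leaf
tensors, which is how attention attribution is computed.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable

import numpy as np

__all__ = ["Tensor", "no_grad", "cat", "conv1d", "maxpool1d"]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the block (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverses numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[np.ndarray], None] | None = None
        self._prev: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: Iterable["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        parents = tuple(p for p in parents if isinstance(p, Tensor))
        track = _GRAD_ENABLED and any(
            p.requires_grad or p._prev for p in parents)
        out = Tensor(data, requires_grad=False)
        if track:
            out._prev = parents
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep (LSTM over time)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node._accum(g)
            if node._backward is not None:
                node._backward_dispatch(g, grads)

    def _backward_dispatch(self, g, grads):
        # _backward fills a local list of (parent, grad) pairs
        for parent, pg in self._backward(g):
            if parent.requires_grad or parent._prev:
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._lift(other)
        a, b = self, other
        out = Tensor._make(a.data + b.data, (a, b), lambda g: [
            (a, _unbroadcast(g, a.shape)), (b, _unbroadcast(g, b.shape))])
        return out

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._make(-a.data, (a,), lambda g: [(a, -g)])

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        a, b = self, other
        return Tensor._make(a.data * b.data, (a, b), lambda g: [
            (a, _unbroadcast(g * b.data, a.shape)),
            (b, _unbroadcast(g * a.data, b.shape))])

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor._lift(other) * self ** -1.0

    def __pow__(self, p: float):
        a = self
        out_data = a.data ** p
        return Tensor._make(out_data, (a,), lambda g: [
            (a, g * p * a.data ** (p - 1))])

    def matmul(self, other: "Tensor") -> "Tensor":
        a, b = self, Tensor._lift(other)
        out_data = np.matmul(a.data, b.data)

        def backward(g):
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            return [(a, _unbroadcast(ga, a.shape)),
                    (b, _unbroadcast(gb, b.shape))]

        return Tensor._make(out_data, (a, b), backward)

    __matmul__ = matmul

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)
        return Tensor._make(out_data, (a,), lambda g: [(a, g * out_data)])

    def log(self):
        a = self
        return Tensor._make(np.log(a.data), (a,), lambda g: [(a, g / a.data)])

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)
        return Tensor._make(out_data, (a,),
                            lambda g: [(a, g * (1.0 - out_data ** 2))])

    def sigmoid(self):
        a = self
        out_data = 0.5 * (np.tanh(0.5 * a.data) + 1.0)  # stable logistic
        return Tensor._make(out_data, (a,),
                            lambda g: [(a, g * out_data * (1.0 - out_data))])

    def relu(self):
        a = self
        mask = a.data > 0
        return Tensor._make(a.data * mask, (a,), lambda g: [(a, g * mask)])

    def xlogx(self):
        """Elementwise x·ln x with the convention 0·ln 0 = 0 (gradient 0)."""
        a = self
        pos = a.data > 0
        safe = np.where(pos, a.data, 1.0)
        out_data = np.where(pos, a.data * np.log(safe), 0.0)
        dgrad = np.where(pos, np.log(safe) + 1.0, 0.0)
        return Tensor._make(out_data, (a,), lambda g: [(a, g * dgrad)])

    # -- reductions / shape ------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is None:
                return [(a, np.broadcast_to(g, a.shape).copy())]
            axes = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                for ax in sorted(ax % a.ndim for ax in axes):
                    g = np.expand_dims(g, ax)
            return [(a, np.broadcast_to(g, a.shape).copy())]

        return Tensor._make(out_data, (a,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else (
            np.prod([self.data.shape[ax] for ax in
                     (axis if isinstance(axis, tuple) else (axis,))]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims=False):
        a = self
        out_data = a.data.max(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            expanded = out_data if keepdims else np.expand_dims(out_data, axis)
            ge = g if keepdims else np.expand_dims(g, axis)
            mask = a.data == expanded
            # split gradient evenly among ties
            counts = mask.sum(axis=axis, keepdims=True)
            return [(a, mask * ge / counts)]

        return Tensor._make(out_data, (a,), backward)

    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return Tensor._make(a.data.reshape(shape), (a,),
                            lambda g: [(a, g.reshape(a.shape))])

    def transpose(self, *axes):
        a = self
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._make(a.data.transpose(axes), (a,),
                            lambda g: [(a, g.transpose(inv))])

    def __getitem__(self, idx):
        a = self
        out_data = a.data[idx]

        def backward(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            return [(a, full)]

        return Tensor._make(out_data, (a,), backward)

    # -- composite ops used by the layers ----------------------------------
    def softmax(self, axis: int = -1):
        a = self
        shifted = a.data - a.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            return [(a, out_data * (g - dot))]

        return Tensor._make(out_data, (a,), backward)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def cat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        pairs = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            pairs.append((t, g[tuple(sl)]))
        return pairs

    return Tensor._make(out_data, tensors, backward)


def conv1d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           dilation: int = 1) -> Tensor:
    """1-D convolution with 'same' zero padding.

    x: (B, C, L); weight: (F, C, k); returns (B, F, L).
    """
    B, C, L = x.shape
    F, C2, k = weight.shape
    if C != C2:
        raise ValueError(f"channel mismatch: input {C}, weight {C2}")
    span = (k - 1) * dilation
    left = span // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (left, span - left)))
    # patches[b, c, j, t] = xp[b, c, t + j*dilation]
    idx = np.arange(L)[None, :] + dilation * np.arange(k)[:, None]
    patches = xp[:, :, idx]  # (B, C, k, L)
    out_data = np.einsum("fcj,bcjl->bfl", weight.data, patches,
                         optimize=True)
    if bias is not None:
        out_data = out_data + bias.data[None, :, None]

    def backward(g):
        pairs = []
        gw = np.einsum("bfl,bcjl->fcj", g, patches, optimize=True)
        pairs.append((weight, gw))
        if bias is not None:
            pairs.append((bias, g.sum(axis=(0, 2))))
        gxp = np.zeros_like(xp)
        gpatch = np.einsum("fcj,bfl->bcjl", weight.data, g, optimize=True)
        for j in range(k):
            gxp[:, :, j * dilation:j * dilation + L] += gpatch[:, :, j, :]
        gx = gxp[:, :, left:left + L]
        pairs.append((x, gx))
        return pairs

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._make(out_data, parents, backward)


def maxpool1d(x: Tensor, pool: int) -> Tensor:
    """Non-overlapping max pooling along the last axis; trailing remainder
    positions are dropped.  x: (B, C, L) -> (B, C, L // pool)."""
    B, C, L = x.shape
    n = L // pool
    trimmed = x.data[:, :, :n * pool].reshape(B, C, n, pool)
    arg = trimmed.argmax(axis=-1)
    out_data = np.take_along_axis(trimmed, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        gt = np.zeros((B, C, n, pool))
        np.put_along_axis(gt, arg[..., None], g[..., None], axis=-1)
        gx = np.zeros_like(x.data)
        gx[:, :, :n * pool] = gt.reshape(B, C, n * pool)
        return [(x, gx)]

    return Tensor._make(out_data, (x,), backward)


def lstm_seq(xw: Tensor, wh: Tensor, b: Tensor, reverse: bool = False
             ) -> Tensor:
    """Unidirectional LSTM over a pre-projected input sequence.

    ``xw`` is the input already multiplied by the input weights,
    (B, n, 4H); ``wh`` the recurrent weights (H, 4H); ``b`` the bias (4H).
    Gate order: input, forget, cell, output.  Returns hidden states
    (B, n, H).  Implemented as a single graph node with an internal
    backpropagation-through-time pass, which keeps the per-timestep work in
    numpy.
    """
    B, n, H4 = xw.shape
    H = H4 // 4
    order = range(n - 1, -1, -1) if reverse else range(n)

    def sig(z):
        return 0.5 * (np.tanh(0.5 * z) + 1.0)

    h = np.zeros((B, H))
    c = np.zeros((B, H))
    cache = [None] * n
    out = np.zeros((B, n, H))
    for t in order:
        g = xw.data[:, t, :] + h @ wh.data + b.data
        i = sig(g[:, :H])
        f = sig(g[:, H:2 * H])
        gg = np.tanh(g[:, 2 * H:3 * H])
        o = sig(g[:, 3 * H:])
        c_prev = c
        c = f * c_prev + i * gg
        h = o * np.tanh(c)
        cache[t] = (i, f, gg, o, c, c_prev, h)
        out[:, t, :] = h

    def backward(grad):
        dxw = np.zeros_like(xw.data)
        dwh = np.zeros_like(wh.data)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        steps = list(order)
        for k, t in enumerate(reversed(steps)):
            i, f, gg, o, ct, c_prev, _ = cache[t]
            dh = grad[:, t, :] + dh_next
            tc = np.tanh(ct)
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc ** 2)
            di = dc * gg
            dgg = dc * i
            df = dc * c_prev
            dc_next = dc * f
            dg = np.concatenate([di * i * (1 - i), df * f * (1 - f),
                                 dgg * (1 - gg ** 2), do * o * (1 - o)],
                                axis=1)
            dxw[:, t, :] = dg
            t_prev = steps[len(steps) - 2 - k] if k < len(steps) - 1 else None
            h_prev = cache[t_prev][6] if t_prev is not None \
                else np.zeros((B, H))
            dwh += h_prev.T @ dg
            dh_next = dg @ wh.data.T
        return [(xw, dxw), (wh, dwh), (b, dxw.sum(axis=(0, 1)))]

    return Tensor._make(out, (xw, wh, b), backward)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy over all elements, numerically stable."""
    z = np.asarray(targets, dtype=np.float64)
    x = logits.data
    loss = np.maximum(x, 0) - x * z + np.log1p(np.exp(-np.abs(x)))
    out_data = np.array(loss.mean())
    n = x.size

    def backward(g):
        p = 0.5 * (np.tanh(0.5 * x) + 1.0)
        return [(logits, g * (p - z) / n)]

    return Tensor._make(out_data, (logits,), backward)
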