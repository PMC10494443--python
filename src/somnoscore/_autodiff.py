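"""Minimal reverse-mode automatic differentiation over numpy arrays.

Internal machinery for the epoch CNN and sequence model.  Supports exactly
the operations those networks need: broadcast add/mul, matmul, ReLU,
sigmoid/tanh, log-softmax, strided 1-D convolution (via im2col), slicing,
concatenation, reshape and axis reductions.  Gradients are exact analytic
expressions; tests cross-check every primitive against central differences.

The graph is a plain DAG of ``Tensor`` nodes; ``Tensor.backward()`` runs a
topological sweep accumulating ``grad`` arrays.  Dtype follows the input
arrays (float32 for training speed, float64 for gradient checks).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv1d", "dropout"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward

    # -- graph traversal ---------------------------------------------------

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- basic algebra -----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.data.dtype))
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.data.dtype))
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.data.dtype))
        return self + (-other)

    def __matmul__(self, other):
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(g @ other.data.swapaxes(-1, -2))
            if other.requires_grad:
                other._accum(self.data.swapaxes(-1, -2) @ g)

        out._backward = bw
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data**p, parents=(self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def bw(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            self._accum(full)

        out._backward = bw
        return out

    # -- shaping -----------------------------------------------------------

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    __rmul__ = __mul__
    __radd__ = __add__

    # -- nonlinearities ----------------------------------------------------

    def relu(self):
        out = Tensor(np.maximum(self.data, 0), parents=(self,))
        out._backward = lambda g: self._accum(g * (self.data > 0))
        return out

    def sigmoid(self):
        # sign-split form avoids exp overflow for large-magnitude inputs
        x = self.data
        s = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                     np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
        out = Tensor(s, parents=(self,))
        out._backward = lambda g: self._accum(g * s * (1 - s))
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, parents=(self,))
        out._backward = lambda g: self._accum(g * (1 - t * t))
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def log_softmax(self, axis: int = -1):
        m = self.data.max(axis=axis, keepdims=True)
        z = self.data - m
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        ls = z - lse
        out = Tensor(ls, parents=(self,))
        sm = np.exp(ls)
        out._backward = lambda g: self._accum(g - sm * g.sum(axis=axis, keepdims=True))
        return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accum(g[tuple(idx)])

    out._backward = bw
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator, train: bool) -> Tensor:
    """Inverted dropout; identity when ``train`` is False or p == 0."""
    if not train or p <= 0:
        return x
    mask = (rng.random(x.data.shape) >= p).astype(x.data.dtype) / (1.0 - p)
    return x * Tensor(mask)


def conv1d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1) -> Tensor:
    """Valid 1-D convolution (cross-correlation) via im2col.

    x: (B, C, W) input, w: (F, C, K) filters, b: (F,) bias.
    Returns (B, F, W_out) with W_out = (W - K) // stride + 1.
    """
    B, C, W = x.data.shape
    F, Cw, K = w.data.shape
    if Cw != C:
        raise ValueError(f"channel mismatch: input {C}, filters {Cw}")
    if W < K:
        raise ValueError(f"input width {W} shorter than kernel {K}")
    wout = (W - K) // stride + 1
    # (B, C, wout, K) strided view, folded to a contiguous (B*wout, C*K) patch
    # matrix so both passes are single GEMMs on contiguous operands
    win = np.lib.stride_tricks.sliding_window_view(x.data, K, axis=2)[:, :, ::stride, :]
    cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(B * wout, C * K)
    wm = w.data.reshape(F, C * K)
    y = cols @ wm.T
    y += b.data
    out = Tensor(np.ascontiguousarray(y.reshape(B, wout, F).transpose(0, 2, 1)), parents=(x, w, b))

    def bw(g):
        gy = np.ascontiguousarray(g.transpose(0, 2, 1)).reshape(B * wout, F)
        if b.requires_grad:
            b._accum(gy.sum(axis=0))
        if w.requires_grad:
            w._accum((gy.T @ cols).reshape(F, C, K))
        if x.requires_grad:
            gcols = (gy @ wm).reshape(B, wout, C, K).transpose(0, 2, 1, 3)  # (B,C,wout,K)
            gx = np.zeros_like(x.data)
            for k in range(K):
                gx[:, :, k : k + wout * stride : stride] += gcols[:, :, :, k]
            x._accum(gx)

    out._backward = bw
    return out
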