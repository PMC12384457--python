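"""Minimal reverse-mode automatic differentiation on numpy arrays.

The network in this package is small (tens of thousands of parameters,
sequences of length ~20 after pooling), so it runs on a compact tape-based
autograd layer: a :class:`Tensor` wraps an ndarray, records the operations
applied to it, and :meth:`Tensor.backward` walks the tape in reverse
topological order accumulating gradients.  Only the operations the model
needs are implemented — elementwise arithmetic with broadcasting, batched
matmul, the activations, reductions, shape manipulation, 1-D convolution
and average pooling.

All arithmetic is float64 and purely deterministic: the only randomness in
a training step (dropout, shuffling, initialisation) comes from explicit
``numpy.random.Generator`` objects passed in by the caller.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "sigmoid",
    "relu",
    "elu",
    "softmax",
    "log_softmax",
    "conv1d",
    "avg_pool1d",
    "dropout",
    "concat_last",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # collapse extra leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray plus the backward closure that produced it."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------

    @classmethod
    def _node(cls, data, parents, backward):
        out = cls(data)
        out._parents = tuple(p for p in parents if isinstance(p, Tensor))
        out.requires_grad = any(p.requires_grad for p in out._parents)
        if out.requires_grad:
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- basic info --------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        def bw(g):
            self._accumulate(g)
            other._accumulate(g)
        return Tensor._node(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accumulate(-g)
        return Tensor._node(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        def bw(g):
            self._accumulate(g * other.data)
            other._accumulate(g * self.data)
        return Tensor._node(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        def bw(g):
            self._accumulate(g / other.data)
            other._accumulate(-g * self.data / (other.data**2))
        return Tensor._node(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        assert np.isscalar(exponent)
        def bw(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))
        return Tensor._node(self.data**exponent, (self,), bw)

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self.data, other.data
        def bw(g):
            self._accumulate(np.matmul(g, np.swapaxes(b, -1, -2)))
            other._accumulate(np.matmul(np.swapaxes(a, -1, -2), g))
        return Tensor._node(np.matmul(a, b), (self, other), bw)

    # -- elementwise functions ---------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)
        def bw(g):
            self._accumulate(g * out_data)
        return Tensor._node(out_data, (self,), bw)

    def log(self):
        def bw(g):
            self._accumulate(g / self.data)
        return Tensor._node(np.log(self.data), (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)
        def bw(g):
            self._accumulate(g * (1.0 - out_data**2))
        return Tensor._node(out_data, (self,), bw)

    # -- reductions ----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))
        return Tensor._node(out_data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape manipulation ---------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        def bw(g):
            self._accumulate(np.asarray(g).reshape(self.data.shape))
        return Tensor._node(self.data.reshape(shape), (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inverse = np.argsort(axes)
        def bw(g):
            self._accumulate(np.transpose(np.asarray(g), inverse))
        return Tensor._node(np.transpose(self.data, axes), (self,), bw)

    def swapaxes(self, a: int, b: int):
        def bw(g):
            self._accumulate(np.swapaxes(np.asarray(g), a, b))
        return Tensor._node(np.swapaxes(self.data, a, b), (self,), bw)

    def __getitem__(self, idx):
        def bw(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            self._accumulate(full)
        return Tensor._node(self.data[idx], (self,), bw)

    def pad_last(self, left: int, right: int):
        """Zero-pad the last axis (used for 'same'/causal convolution)."""
        width = [(0, 0)] * (self.data.ndim - 1) + [(left, right)]
        T = self.data.shape[-1]
        def bw(g):
            sl = (Ellipsis, slice(left, left + T))
            self._accumulate(np.asarray(g)[sl])
        return Tensor._node(np.pad(self.data, width), (self,), bw)

    def detached(self) -> np.ndarray:
        return self.data.copy()


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- activations -------------------------------------------------------------


def sigmoid(t: Tensor) -> Tensor:
    t = as_tensor(t)
    out_data = 1.0 / (1.0 + np.exp(-t.data))
    def bw(g):
        t._accumulate(g * out_data * (1.0 - out_data))
    return Tensor._node(out_data, (t,), bw)


def relu(t: Tensor) -> Tensor:
    t = as_tensor(t)
    mask = t.data > 0
    def bw(g):
        t._accumulate(g * mask)
    return Tensor._node(t.data * mask, (t,), bw)


def elu(t: Tensor, alpha: float = 1.0) -> Tensor:
    t = as_tensor(t)
    neg = alpha * (np.exp(np.minimum(t.data, 0.0)) - 1.0)
    out_data = np.where(t.data > 0, t.data, neg)
    def bw(g):
        t._accumulate(g * np.where(t.data > 0, 1.0, neg + alpha))
    return Tensor._node(out_data, (t,), bw)


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    shift = as_tensor(t).data.max(axis=axis, keepdims=True)  # constant shift
    e = (t - Tensor(shift)).exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(t: Tensor, axis: int = -1) -> Tensor:
    shift = as_tensor(t).data.max(axis=axis, keepdims=True)
    z = t - Tensor(shift)
    return z - z.exp().sum(axis=axis, keepdims=True).log()


# -- structured operations ----------------------------------------------------


def conv1d(
    x: Tensor,
    w: Tensor,
    bias: Tensor | None = None,
    pad: int | tuple[int, int] | str = 0,
    dilation: int = 1,
) -> Tensor:
    """Cross-correlation along the last axis.

    x: (B, C_in, T), w: (C_out, C_in, K).  ``pad`` may be an int, an
    asymmetric (left, right) pair, or "same" (output length equals input
    length; for even K the extra pad sample goes on the left).
    """
    x, w = as_tensor(x), as_tensor(w)
    bias = as_tensor(bias) if bias is not None else None
    B, Ci, T = x.shape
    Co, Ciw, K = w.shape
    if Ci != Ciw:
        raise ValueError(f"conv1d channel mismatch: input {Ci}, weight {Ciw}")
    span = (K - 1) * dilation
    if pad == "same":
        left, right = span - span // 2, span // 2
    elif isinstance(pad, tuple):
        left, right = pad
    else:
        left = right = int(pad)
    xp = np.pad(x.data, ((0, 0), (0, 0), (left, right))) if (left or right) else x.data
    T_p = xp.shape[-1]
    T_out = T_p - span
    if T_out < 1:
        raise ValueError(f"conv1d: input length {T} too short for kernel {K}")

    # FFT path for long undilated kernels, tap loop for short/dilated ones
    use_fft = dilation == 1 and K * T_out * Ci * Co * B > 2_000_000
    if use_fft:
        from scipy.fft import next_fast_len

        L = next_fast_len(T_p)
        xp_hat = np.fft.rfft(xp, n=L)  # (B, Ci, L')
        w_hat = np.fft.rfft(w.data, n=L)  # (Co, Ci, L')
        # cross-correlation: multiply by the conjugate spectrum
        out_data = np.fft.irfft(
            np.einsum("bif,oif->bof", xp_hat, np.conj(w_hat), optimize=True), n=L
        )[:, :, :T_out]
    else:
        out_data = np.zeros((B, Co, T_out))
        for k in range(K):
            out_data += np.einsum(
                "oi,bit->bot", w.data[:, :, k],
                xp[:, :, k * dilation : k * dilation + T_out],
                optimize=True,
            )
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, Co, 1)

    def bw(g):
        g = np.ascontiguousarray(g)
        if use_fft:
            L = next_fast_len(T_p)
            g_hat = np.fft.rfft(g, n=L)
            if w.requires_grad:
                dW = np.fft.irfft(
                    np.einsum("bof,bif->oif", np.conj(g_hat), xp_hat, optimize=True),
                    n=L,
                )[:, :, :K]
                w._accumulate(dW)
            if x.requires_grad:
                dxp = np.fft.irfft(
                    np.einsum("bof,oif->bif", g_hat, w_hat, optimize=True), n=L
                )[:, :, :T_p]
                x._accumulate(dxp[:, :, left : left + T] if (left or right) else dxp)
        else:
            if w.requires_grad:
                dW = np.empty_like(w.data)
                for k in range(K):
                    dW[:, :, k] = np.einsum(
                        "bot,bit->oi", g,
                        xp[:, :, k * dilation : k * dilation + T_out],
                        optimize=True,
                    )
                w._accumulate(dW)
            if x.requires_grad:
                dxp = np.zeros_like(xp)
                for k in range(K):
                    dxp[:, :, k * dilation : k * dilation + T_out] += np.einsum(
                        "oi,bot->bit", w.data[:, :, k], g, optimize=True
                    )
                x._accumulate(dxp[:, :, left : left + T] if (left or right) else dxp)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2)))

    parents = (x, w) if bias is None else (x, w, bias)
    return Tensor._node(out_data, parents, bw)


def avg_pool1d(x: Tensor, p: int) -> Tensor:
    """Non-overlapping average pooling over the last axis (floor division)."""
    x = as_tensor(x)
    *lead, T = x.shape
    T_out = T // p
    if T_out < 1:
        raise ValueError(f"avg_pool1d: length {T} shorter than window {p}")
    trimmed = x[..., : T_out * p]
    return trimmed.reshape(*lead, T_out, p).mean(axis=-1)


def dropout(x: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or rate <= 0.0:
        return as_tensor(x)
    keep = 1.0 - rate
    mask = (rng.random(as_tensor(x).shape) < keep) / keep
    return as_tensor(x) * Tensor(mask)


def concat_last(tensors: list[Tensor]) -> Tensor:
    """Concatenate along the last axis."""
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[-1] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    def bw(g):
        g = np.asarray(g)
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            t._accumulate(g[..., a:b])
    data = np.concatenate([t.data for t in tensors], axis=-1)
    return Tensor._node(data, tuple(tensors), bw)
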