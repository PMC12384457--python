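"""Neural-network building blocks on top of the autodiff tensors.

Conventions: batched sequence features are (batch, feature, time) for the
convolutional stages and (batch, time, feature) for attention; layers state
which they expect.  All parameters are float64 tensors created from an
explicit ``numpy.random.Generator`` so that a fixed seed reproduces the
model bit-for-bit.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, as_tensor, conv1d, sigmoid, softmax

__all__ = [
    "Module",
    "Linear",
    "Conv1d",
    "BatchNorm",
    "LayerNorm",
    "MultiHeadSelfAttention",
    "glorot",
]


def glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Module:
    """Parameter container with recursive traversal and train/eval state."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()

        def walk(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)

        walk(self)
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]

        def walk(obj):
            if isinstance(obj, Module):
                mods.append(obj)
                for v in vars(obj).values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)

        for v in vars(self).values():
            walk(v)
        return mods

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array mapping of parameters (checkpoint payload)."""
        return {f"param_{i}": p.data for i, p in enumerate(self.parameters())}

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            src = np.asarray(arrays[f"param_{i}"])
            if src.shape != p.data.shape:
                raise ValueError(
                    f"checkpoint shape mismatch at param_{i}: "
                    f"{src.shape} vs {p.data.shape}"
                )
            p.data = src.astype(np.float64)


class Linear(Module):
    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int, bias: bool = True):
        super().__init__()
        self.W = glorot(rng, (d_in, d_out), d_in, d_out)
        self.b = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = as_tensor(x) @ self.W
        if self.b is not None:
            out = out + self.b
        return out


class Conv1d(Module):
    """1-D convolution over the last axis of a (B, C, T) tensor."""

    def __init__(
        self,
        rng: np.random.Generator,
        c_in: int,
        c_out: int,
        kernel: int,
        pad: int | tuple[int, int] | str = "same",
        dilation: int = 1,
        bias: bool = True,
    ):
        super().__init__()
        fan_in, fan_out = c_in * kernel, c_out * kernel
        self.W = glorot(rng, (c_out, c_in, kernel), fan_in, fan_out)
        self.b = Tensor(np.zeros(c_out), requires_grad=True) if bias else None
        self.pad = pad
        self.dilation = dilation

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.W, bias=self.b, pad=self.pad, dilation=self.dilation)


class BatchNorm(Module):
    """Batch normalisation per feature map of a (B, F, T) tensor.

    Statistics are taken over batch and time.  Running statistics use
    momentum 0.9 (running <- 0.9 running + 0.1 batch) so that inference
    statistics track the training distribution within tens of optimiser
    steps — at the small step counts of this pipeline a slower schedule
    leaves evaluation-mode normalisation stale long after the weights have
    converged.  Epsilon follows the compact EEG-model convention (1e-3).
    """

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-3):
        super().__init__()
        self.gamma = Tensor(np.ones(n_features), requires_grad=True)
        self.beta = Tensor(np.zeros(n_features), requires_grad=True)
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        # feature maps live on axis 1; statistics pool every other axis
        axes = (0,) + tuple(range(2, x.ndim))
        bshape = (1, -1) + (1,) * (x.ndim - 2)
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=axes, keepdims=True)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mu.data.ravel()
            )
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var.data.ravel()
            )
        else:
            mu = Tensor(self.running_mean.reshape(bshape))
            var = Tensor(self.running_var.reshape(bshape))
        xhat = (x - mu) * (var + self.eps) ** -0.5
        return xhat * self.gamma.reshape(bshape) + self.beta.reshape(bshape)


class LayerNorm(Module):
    """Layer normalisation over the last (feature) axis."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        xhat = (x - mu) * (var + self.eps) ** -0.5
        return xhat * self.gamma + self.beta


class MultiHeadSelfAttention(Module):
    """Multi-head self-attention with an optional additive mask.

    The inner dimension is heads x head_dim, which may be smaller than the
    model dimension (here 2 x 8 = 16 against 32 feature maps): Q/K/V project
    d_model -> inner and the output projects inner -> d_model so residual
    connections stay in d_model space.  Input and output are (B, T, d_model).
    """

    def __init__(
        self,
        rng: np.random.Generator,
        d_model: int,
        n_heads: int = 2,
        head_dim: int = 8,
    ):
        super().__init__()
        inner = n_heads * head_dim
        self.n_heads = n_heads
        self.head_dim = head_dim
        self.q = Linear(rng, d_model, inner)
        self.k = Linear(rng, d_model, inner)
        self.v = Linear(rng, d_model, inner)
        self.out = Linear(rng, inner, d_model)

    def attention_weights(self, x, mask: np.ndarray | None = None) -> np.ndarray:
        """Post-softmax attention map (B, heads, T, T); diagnostic, no grads."""
        return self._forward(as_tensor(x), mask, return_weights=True)[1]

    def __call__(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        return self._forward(as_tensor(x), mask, return_weights=False)[0]

    def _forward(self, x: Tensor, mask, return_weights):
        B, T, _ = x.shape
        H, dh = self.n_heads, self.head_dim

        def split(t: Tensor) -> Tensor:  # (B, T, H*dh) -> (B, H, T, dh)
            return t.reshape(B, T, H, dh).transpose(0, 2, 1, 3)

        q, k, v = split(self.q(x)), split(self.k(x)), split(self.v(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        if mask is not None:
            mask = np.asarray(mask, dtype=np.float64)
            if mask.shape != (T, T):
                raise ValueError(f"mask must be ({T}, {T}), got {mask.shape}")
            if np.any(np.all(mask < 0, axis=1)):
                raise ValueError("attention mask has a fully masked row")
            scores = scores + Tensor(mask)
        attn = softmax(scores, axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, T, H * dh)
        return self.out(ctx), attn.data
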