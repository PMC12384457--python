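"""GATE: graph-attentional temporal encoding of raw EEG epochs.

The block maps a raw epoch X (time x electrodes) to a compact feature
sequence F_GATE (T' x F2) in four stages:

1. Chebyshev graph convolution per time step, Z_t = sum_k T_k(A_hat) X_t W_k,
   with scalar per-order weights so the electrode axis is preserved
   (Z is time x electrodes).
2. Squeeze-and-excitation channel attention over the electrodes:
   s = temporal mean per electrode, w = sigmoid(W2 relu(W1 s)), Z' = Z * w.
3. A three-stage temporal-spatial convolutional encoder (EEGNet-style):
   length-kt temporal convolution per electrode into F1 maps (+BN), a
   depthwise spatial convolution spanning all electrodes with multiplier 2
   into F2 maps (+BN, ELU, average-pool 8), and a length-16 temporal
   convolution (+BN, ELU, average-pool P=7, dropout).

Both temporal convolutions use 'same' padding, so the output length is
T' = floor(floor(T/8)/7); T = 1125 gives T' = 20.

The module class operates on batches; the module-level functions expose the
same computations on single (time x electrodes) arrays for inspection and
testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .montage import SpatialGraph
from .nn import Tensor, avg_pool1d, elu

__all__ = [
    "GateConfig",
    "GateBlock",
    "cheb_graph_conv",
    "se_channel_attention",
    "temporal_spatial_encode",
    "gate_forward",
    "gate_output_length",
]


@dataclass
class GateConfig:
    K: int = 3  # Chebyshev order
    F1: int = 16  # temporal filters
    kt: int = 64  # temporal kernel length
    depth_multiplier: int = 2
    pool1: int = 8
    pool2: int = 7  # P
    long_kernel: int = 16
    dropout_rate: float = 0.3
    se_reduction: int = 4

    def __post_init__(self):
        for name in ("K", "F1", "kt", "depth_multiplier", "pool1", "pool2",
                     "long_kernel", "se_reduction"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def F2(self) -> int:
        return self.F1 * self.depth_multiplier


def gate_output_length(T: int, cfg: GateConfig) -> int:
    """Sequence length after the two temporal poolings: floor(floor(T/p1)/p2)."""
    return (T // cfg.pool1) // cfg.pool2


class GateBlock(nn.Module):
    """Trainable GATE block operating on (batch, electrodes, time) input."""

    def __init__(
        self,
        rng: np.random.Generator,
        graph: SpatialGraph,
        cfg: GateConfig,
        use_channel_attention: bool = True,
        use_ts_encoder: bool = True,
    ):
        super().__init__()
        if graph.A_hat is None or len(graph.cheb_basis) < cfg.K:
            raise ValueError(
                "graph must carry A_hat and a Chebyshev basis of order >= K"
            )
        self.cfg = cfg
        self.C = graph.n_channels
        self.use_channel_attention = use_channel_attention
        self.use_ts_encoder = use_ts_encoder
        # stacked basis as a constant (K, C, C)
        self.basis = np.stack(graph.cheb_basis[: cfg.K])
        # scalar weight per Chebyshev order (one input/output graph map);
        # initialised near identity so the raw signal passes through at start
        w0 = np.zeros(cfg.K)
        w0[0] = 1.0
        self.cheb_w = Tensor(w0 + rng.normal(0.0, 0.01, cfg.K), requires_grad=True)
        if use_channel_attention:
            hidden = max(1, self.C // cfg.se_reduction)
            self.se_W1 = nn.glorot(rng, (hidden, self.C), self.C, hidden)
            self.se_W2 = nn.glorot(rng, (self.C, hidden), hidden, self.C)
        if use_ts_encoder:
            self.conv_t = nn.Conv1d(rng, 1, cfg.F1, cfg.kt, pad="same")
            self.bn1 = nn.BatchNorm(cfg.F1)
            self.depth_w = nn.glorot(
                rng, (cfg.F1, 1, self.C, cfg.depth_multiplier),
                self.C, cfg.depth_multiplier,
            )
            self.bn2 = nn.BatchNorm(cfg.F2)
            self.conv_long = nn.Conv1d(rng, cfg.F2, cfg.F2, cfg.long_kernel, pad="same")
            self.bn3 = nn.BatchNorm(cfg.F2)

    @property
    def out_dim(self) -> int:
        """Feature dimension handed to HADTE (F2, or C when the encoder is off)."""
        return self.cfg.F2 if self.use_ts_encoder else self.C

    def cheb(self, x: Tensor) -> Tensor:
        """Graph convolution per time step on (B, C, T)."""
        out = None
        for k in range(self.cfg.K):
            term = (Tensor(self.basis[k]) @ x) * self.cheb_w[k]
            out = term if out is None else out + term
        return out

    def se(self, z: Tensor) -> Tensor:
        s = z.mean(axis=2)  # (B, C)
        h = nn.relu(s @ self.se_W1.swapaxes(0, 1))
        w = nn.sigmoid(h @ self.se_W2.swapaxes(0, 1))  # (B, C)
        B, C = w.shape
        return z * w.reshape(B, C, 1)

    def encode(self, zp: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        """Temporal-spatial encoder: (B, C, T) -> (B, F2, T')."""
        cfg = self.cfg
        B, C, T = zp.shape
        if T < cfg.kt:
            raise ValueError(f"time length {T} shorter than temporal kernel {cfg.kt}")
        # stage 1: per-electrode temporal convolution, shared weights
        h = self.conv_t(zp.reshape(B * C, 1, T))  # (B*C, F1, T)
        h = h.reshape(B, C, cfg.F1, T).transpose(0, 2, 1, 3)  # (B, F1, C, T)
        h = self.bn1(h)
        # stage 2: depthwise spatial convolution spanning all C electrodes
        hm = h.transpose(1, 0, 3, 2)  # (F1, B, T, C)
        hm = hm @ self.depth_w  # (F1, B, T, M) via (F1, 1, C, M)
        hm = hm.transpose(1, 0, 3, 2)  # (B, F1, M, T)
        h = hm.reshape(B, cfg.F2, T)
        h = avg_pool1d(elu(self.bn2(h)), cfg.pool1)
        # stage 3: long temporal convolution
        h = avg_pool1d(elu(self.bn3(self.conv_long(h))), cfg.pool2)
        h = nn.dropout(h, cfg.dropout_rate,
                       rng if rng is not None else np.random.default_rng(0),
                       self.training)
        return h

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        """(B, C, T) -> (B, out_dim, T')."""
        z = self.cheb(x)
        if self.use_channel_attention:
            z = self.se(z)
        if self.use_ts_encoder:
            return self.encode(z, rng)
        # bypass adapter: average-pool the raw-length sequence down to T'
        return avg_pool1d(z, self.cfg.pool1 * self.cfg.pool2)


# -- single-trial functional surface (numpy in, numpy out) --------------------


def cheb_graph_conv(X: np.ndarray, graph: SpatialGraph, weights) -> np.ndarray:
    """Z_t = sum_k T_k(A_hat) X_t W_k on a (time, electrodes) array.

    ``weights`` is one scalar per Chebyshev order (scalar node features).
    """
    X = np.asarray(X, dtype=float)
    weights = np.asarray(weights, dtype=float).ravel()
    K = len(weights)
    if len(graph.cheb_basis) < K:
        raise ValueError(f"graph carries {len(graph.cheb_basis)} basis matrices, "
                         f"need {K}")
    if X.shape[1] != graph.n_channels:
        raise ValueError(
            f"electrode count {X.shape[1]} does not match graph {graph.n_channels}"
        )
    Z = np.zeros_like(X)
    for k in range(K):
        # T_k symmetric: (T_k X_t) stacked over t equals X @ T_k
        Z += weights[k] * X @ graph.cheb_basis[k]
    return Z


def se_channel_attention(
    Z: np.ndarray, weights: tuple[np.ndarray, np.ndarray]
) -> np.ndarray:
    """SE gating over electrodes on a (time, electrodes) array."""
    W1, W2 = (np.asarray(w, dtype=float) for w in weights)
    s = Z.mean(axis=0)  # per-electrode temporal average
    h = np.maximum(W1 @ s, 0.0)
    w = 1.0 / (1.0 + np.exp(-(W2 @ h)))
    return Z * w[None, :]


def temporal_spatial_encode(
    Zp: np.ndarray, block: GateBlock, training: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Run the encoder of ``block`` on one (time, electrodes) array."""
    block.train() if training else block.eval()
    t = Tensor(np.asarray(Zp, dtype=float).T[None])  # (1, C, T)
    out = block.encode(t, rng)
    return out.data[0].T  # (T', F2)


def gate_forward(
    X: np.ndarray, block: GateBlock, training: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Full GATE on one (time, electrodes) array -> (T', out_dim)."""
    block.train() if training else block.eval()
    t = Tensor(np.asarray(X, dtype=float).T[None])
    return block(t, rng).data[0].T
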