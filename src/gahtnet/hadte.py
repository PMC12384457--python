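"""HADTE: hierarchical attention-guided deep temporal feature encoding.

Takes the GATE feature sequence (T' x F2) through four stages:

1. Residual-ECA: efficient channel attention — a kernel-3 1-D convolution
   over the global-average-pooled map descriptor, sigmoid-gated, added back
   residually: F_eca = F + ECA(F).
2. Local masked multi-head self-attention: 2 heads of dimension 8 with an
   additive band mask M_ij = 0 if |i-j| <= w*d else -inf (w=16, d=1), and a
   residual connection.  No layer norm at this stage.
3. Global multi-head self-attention with pre-layer-norm and residual:
   F_global = MHA(LN(F_local)) + F_local.
4. A causal dilated TCN (2 residual blocks, kernel 4, dilations 1 and 2,
   ELU, dropout); the final representation is the last-position feature
   vector.

The attention carries no positional encoding; temporal order is supplied by
the convolutions around it.  Each stage can be bypassed with an exact
identity, which is what makes ablation variants well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor, as_tensor, avg_pool1d, dropout, elu

__all__ = [
    "HadteConfig",
    "AttentionMask",
    "build_local_mask",
    "HadteBlock",
    "residual_eca",
    "local_masked_attention",
    "global_attention",
    "tcn_forward",
    "hadte_forward",
]

NEG_INF = -1e9  # additive mask sentinel applied to pre-softmax logits


@dataclass
class HadteConfig:
    w: int = 16  # local attention window
    d: int = 1  # dilation of the window
    n_heads: int = 2
    head_dim: int = 8
    eca_kernel: int = 3
    tcn_blocks: int = 2
    tcn_kernel: int = 4
    tcn_dropout: float = 0.3

    def __post_init__(self):
        if self.w < 0:
            raise ValueError("window size must be >= 0")
        if self.d < 1:
            raise ValueError("dilation must be >= 1")
        if self.eca_kernel % 2 == 0:
            raise ValueError(f"ECA kernel must be odd, got {self.eca_kernel}")
        if self.tcn_kernel < 2:
            raise ValueError("TCN kernel must be >= 2 to grow a receptive field")


@dataclass
class AttentionMask:
    """Additive band mask: 0 on |i-j| <= w*d, a large negative value elsewhere."""

    M: np.ndarray

    def __post_init__(self):
        M = np.asarray(self.M, dtype=np.float64)
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError(f"mask must be square, got {M.shape}")
        self.M = M

    @property
    def n_unmasked(self) -> int:
        return int((self.M == 0).sum())


def build_local_mask(T: int, w: int, d: int = 1) -> AttentionMask:
    """Band mask of half-width w*d over a length-T sequence."""
    if T < 1:
        raise ValueError(f"sequence length must be >= 1, got {T}")
    idx = np.arange(T)
    band = np.abs(idx[:, None] - idx[None, :]) <= w * d
    return AttentionMask(np.where(band, 0.0, NEG_INF))


class ECA(nn.Module):
    """Efficient channel attention gate over the feature-map axis."""

    def __init__(self, rng: np.random.Generator, kernel: int = 3):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError(f"ECA kernel must be odd, got {kernel}")
        self.conv = nn.Conv1d(rng, 1, 1, kernel, pad="same", bias=False)

    def __call__(self, x: Tensor) -> Tensor:
        """Gated copy of x, gate in (0,1); x is (B, T, F)."""
        B, T, F = x.shape
        s = x.mean(axis=1)  # (B, F) pooled descriptor
        g = nn.sigmoid(self.conv(s.reshape(B, 1, F)).reshape(B, F))
        return x * g.reshape(B, 1, F)


class TCNBlock(nn.Module):
    """One causal dilated residual block: two conv->BN->ELU->dropout passes."""

    def __init__(self, rng: np.random.Generator, n_filters: int, kernel: int,
                 dilation: int, drop: float):
        super().__init__()
        pad = ((kernel - 1) * dilation, 0)  # left-only: causal
        self.conv1 = nn.Conv1d(rng, n_filters, n_filters, kernel, pad=pad,
                               dilation=dilation)
        self.bn1 = nn.BatchNorm(n_filters)
        self.conv2 = nn.Conv1d(rng, n_filters, n_filters, kernel, pad=pad,
                               dilation=dilation)
        self.bn2 = nn.BatchNorm(n_filters)
        self.drop = drop

    def __call__(self, x: Tensor, rng: np.random.Generator) -> Tensor:
        h = dropout(elu(self.bn1(self.conv1(x))), self.drop, rng, self.training)
        h = dropout(elu(self.bn2(self.conv2(h))), self.drop, rng, self.training)
        return x + h


class HadteBlock(nn.Module):
    """Trainable HADTE block on (batch, T', F) input, producing (batch, F)."""

    def __init__(
        self,
        rng: np.random.Generator,
        d_model: int,
        cfg: HadteConfig,
        use_residual_eca: bool = True,
        use_local_mha: bool = True,
        use_global_mha: bool = True,
        use_tcn: bool = True,
    ):
        super().__init__()
        self.cfg = cfg
        self.d_model = d_model
        self.use_residual_eca = use_residual_eca
        self.use_local_mha = use_local_mha
        self.use_global_mha = use_global_mha
        self.use_tcn = use_tcn
        if use_residual_eca:
            self.eca = ECA(rng, cfg.eca_kernel)
        if use_local_mha:
            self.local_mha = nn.MultiHeadSelfAttention(
                rng, d_model, cfg.n_heads, cfg.head_dim
            )
        if use_global_mha:
            self.ln = nn.LayerNorm(d_model)
            self.global_mha = nn.MultiHeadSelfAttention(
                rng, d_model, cfg.n_heads, cfg.head_dim
            )
        if use_tcn:
            self.tcn = [
                TCNBlock(rng, d_model, cfg.tcn_kernel, 2**i, cfg.tcn_dropout)
                for i in range(cfg.tcn_blocks)
            ]

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        rng = rng if rng is not None else np.random.default_rng(0)
        B, T, _F = x.shape
        if self.use_residual_eca:
            x = x + self.eca(x)
        if self.use_local_mha:
            mask = build_local_mask(T, self.cfg.w, self.cfg.d).M
            x = self.local_mha(x, mask) + x
        if self.use_global_mha:
            x = self.global_mha(self.ln(x)) + x
        if self.use_tcn:
            h = x.transpose(0, 2, 1)  # (B, F, T) for the convolutions
            for block in self.tcn:
                h = block(h, rng)
            return h[:, :, -1]
        return x[:, -1, :]  # TCN bypass: last-position feature vector


# -- single-trial functional surface (numpy in, numpy out) --------------------


def _single(x: np.ndarray) -> Tensor:
    return Tensor(np.asarray(x, dtype=float)[None])  # add batch axis


def residual_eca(F: np.ndarray, eca: ECA) -> np.ndarray:
    """F + ECA(F) on a (T', F2) array."""
    eca.eval()
    t = _single(F)
    return (t + eca(t)).data[0]


def local_masked_attention(
    F_eca: np.ndarray, mask: AttentionMask, mha: nn.MultiHeadSelfAttention
) -> np.ndarray:
    """Masked multi-head self-attention with residual on a (T', F2) array."""
    if mask.M.shape[0] != np.asarray(F_eca).shape[0]:
        raise ValueError(
            f"mask size {mask.M.shape[0]} does not match sequence "
            f"{np.asarray(F_eca).shape[0]}"
        )
    t = _single(F_eca)
    return (mha(t, mask.M) + t).data[0]


def global_attention(
    F_local: np.ndarray, mha: nn.MultiHeadSelfAttention, ln: nn.LayerNorm
) -> np.ndarray:
    """Pre-layer-norm global attention with residual on a (T', F2) array."""
    t = _single(F_local)
    return (mha(ln(t)) + t).data[0]


def tcn_forward(
    F_global: np.ndarray, blocks: list[TCNBlock], training: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Causal TCN stack on a (T', F) array -> last-position (F,) vector."""
    rng = rng if rng is not None else np.random.default_rng(0)
    h = _single(F_global).transpose(0, 2, 1)
    for b in blocks:
        b.train() if training else b.eval()
        h = b(h, rng)
    return h.data[0, :, -1]


def hadte_forward(
    F_GATE: np.ndarray, block: HadteBlock, training: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Full HADTE on one (T', F) array -> (F,) feature vector."""
    block.train() if training else block.eval()
    return block(_single(F_GATE), rng).data[0]
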