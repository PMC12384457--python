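"""HADTE block: ECA residual, banded/global attention and the causal TCN."""

import numpy as np
import pytest

from gahtnet.hadte import (
    ECA,
    AttentionMask,
    HadteBlock,
    HadteConfig,
    TCNBlock,
    build_local_mask,
    global_attention,
    hadte_forward,
    local_masked_attention,
    residual_eca,
    tcn_forward,
)
from gahtnet.nn import LayerNorm, MultiHeadSelfAttention, Tensor


class TestLocalMask:
    def test_window_covering_sequence_masks_nothing(self):
        m = build_local_mask(10, w=9, d=1)
        assert np.array_equal(m.M, np.zeros((10, 10)))

    def test_standard_geometry_has_388_unmasked_entries(self):
        m = build_local_mask(20, w=16, d=1)
        assert m.n_unmasked == 388

    def test_zero_window_keeps_only_diagonal(self):
        m = build_local_mask(7, w=0, d=1)
        assert m.n_unmasked == 7
        assert np.all(np.diag(m.M) == 0)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            build_local_mask(0, w=3)

    @pytest.mark.parametrize("T,w,d", [(5, 1, 1), (20, 16, 1), (33, 3, 2), (64, 5, 3)])
    def test_band_structure_matches_enumeration(self, T, w, d):
        m = build_local_mask(T, w, d).M
        for i in range(T):
            for j in range(T):
                if abs(i - j) <= w * d:
                    assert m[i, j] == 0
                else:
                    assert m[i, j] < 0
        assert np.array_equal(m, m.T)
        assert np.all(np.diag(m) == 0)


class TestResidualECA:
    def test_zero_conv_weights_scale_by_three_halves(self, rng):
        eca = ECA(rng, kernel=3)
        eca.conv.W.data[:] = 0.0
        F = rng.normal(size=(12, 8))
        assert np.allclose(residual_eca(F, eca), 1.5 * F)

    def test_residual_branch_is_bounded_gate(self, rng):
        eca = ECA(rng, kernel=3)
        F = rng.normal(size=(12, 8))
        delta = residual_eca(F, eca) - F
        ratio = delta / np.where(F == 0, 1.0, F)
        assert np.all(ratio > 0) and np.all(ratio < 1)

    def test_matches_explicit_gap_conv_sigmoid_pipeline(self, rng):
        eca = ECA(rng, kernel=3)
        F = rng.normal(size=(10, 6))
        s = F.mean(axis=0)  # (6,)
        w = eca.conv.W.data[0, 0]  # (3,)
        sp = np.pad(s, 1)
        conv = np.array([w @ sp[i : i + 3] for i in range(6)])
        gate = 1 / (1 + np.exp(-conv))
        assert np.allclose(residual_eca(F, eca), F + F * gate[None, :])

    def test_even_kernel_rejected(self, rng):
        with pytest.raises(ValueError, match="odd"):
            ECA(rng, kernel=4)
        with pytest.raises(ValueError, match="odd"):
            HadteConfig(eca_kernel=2)


class TestLocalAttention:
    def test_zero_value_and_output_projections_reduce_to_identity(self, rng):
        mha = MultiHeadSelfAttention(rng, 8, 2, 4)
        mha.v.W.data[:] = 0
        mha.v.b.data[:] = 0
        mha.out.b.data[:] = 0
        F = rng.normal(size=(6, 8))
        out = local_masked_attention(F, build_local_mask(6, 2), mha)
        assert np.allclose(out, F)

    def test_full_window_equals_unmasked_global_attention(self, rng):
        mha = MultiHeadSelfAttention(rng, 8, 2, 4)
        F = rng.normal(size=(9, 8))
        local = local_masked_attention(F, build_local_mask(9, 9), mha)
        t = Tensor(F[None])
        unmasked = (mha(t) + t).data[0]
        assert np.abs(local - unmasked).max() < 1e-6

    def test_mask_size_mismatch_rejected(self, rng):
        mha = MultiHeadSelfAttention(rng, 8, 2, 4)
        with pytest.raises(ValueError, match="mask"):
            local_masked_attention(rng.normal(size=(6, 8)),
                                   build_local_mask(5, 2), mha)

    def test_attention_rows_are_masked_distributions(self, rng):
        mha = MultiHeadSelfAttention(rng, 8, 2, 4)
        F = rng.normal(size=(7, 8))
        mask = build_local_mask(7, 1).M
        wts = mha.attention_weights(Tensor(F[None]), mask)
        assert np.allclose(wts.sum(axis=-1), 1.0)
        assert np.all(wts[:, :, mask < 0] < 1e-12)


class TestGlobalAttention:
    def test_zero_projections_reduce_to_identity(self, rng):
        mha = MultiHeadSelfAttention(rng, 8, 2, 4)
        ln = LayerNorm(8)
        mha.v.W.data[:] = 0
        mha.v.b.data[:] = 0
        mha.out.b.data[:] = 0
        F = rng.normal(size=(5, 8))
        assert np.allclose(global_attention(F, mha, ln), F)

    def test_permutation_equivariance_without_positional_encoding(self, rng):
        mha = MultiHeadSelfAttention(rng, 8, 2, 4)
        ln = LayerNorm(8)
        F = rng.normal(size=(6, 8))
        perm = rng.permutation(6)
        out_perm = global_attention(F[perm], mha, ln)
        out = global_attention(F, mha, ln)
        assert np.abs(out_perm - out[perm]).max() < 1e-10


class TestTCN:
    def test_causality_future_perturbation_does_not_leak_backward(self, rng):
        block = TCNBlock(rng, n_filters=4, kernel=2, dilation=1, drop=0.0)
        block.eval()
        x = rng.normal(size=(8, 4))
        y1 = np.stack([r for r in _tcn_all_positions(block, x)])
        x2 = x.copy()
        x2[5:] += rng.normal(size=(3, 4))
        y2 = np.stack([r for r in _tcn_all_positions(block, x2)])
        assert np.abs(y1[:5] - y2[:5]).max() < 1e-12

    def test_single_block_matches_hand_convolution_loop(self, rng):
        block = TCNBlock(rng, n_filters=2, kernel=2, dilation=1, drop=0.0)
        block.eval()
        x = rng.normal(size=(4, 2))
        out = np.stack(list(_tcn_all_positions(block, x)))

        def conv_causal(h, conv, bn):
            hp = np.vstack([np.zeros((1, h.shape[1])), h])  # left pad 1
            pre = np.stack(
                [
                    conv.W.data[:, :, 0] @ hp[t] + conv.W.data[:, :, 1] @ hp[t + 1]
                    + conv.b.data
                    for t in range(h.shape[0])
                ]
            )
            norm = (pre - bn.running_mean) / np.sqrt(bn.running_var + bn.eps)
            act = norm * bn.gamma.data + bn.beta.data
            return np.where(act > 0, act, np.exp(np.minimum(act, 0)) - 1)

        h = conv_causal(x, block.conv1, block.bn1)
        h = conv_causal(h, block.conv2, block.bn2)
        assert np.abs(out - (x + h)).max() < 1e-10

    def test_eval_mode_repeated_calls_identical(self, rng):
        cfg = HadteConfig()
        blocks = [TCNBlock(rng, 6, cfg.tcn_kernel, 2**i, cfg.tcn_dropout)
                  for i in range(2)]
        F = rng.normal(size=(10, 6))
        a = tcn_forward(F, blocks, training=False)
        b = tcn_forward(F, blocks, training=False)
        assert np.array_equal(a, b)

    def test_kernel_below_two_rejected(self):
        with pytest.raises(ValueError, match="kernel"):
            HadteConfig(tcn_kernel=1)


def _tcn_all_positions(block, x):
    """Run one TCN block and yield every output position (T, F) -> rows."""
    h = Tensor(x.T[None])
    out = block(h, np.random.default_rng(0)).data[0].T
    yield from out


class TestHadteForward:
    def test_shape_contract_20x32_to_32(self, rng):
        block = HadteBlock(rng, d_model=32, cfg=HadteConfig())
        out = hadte_forward(rng.normal(size=(20, 32)), block)
        assert out.shape == (32,)
        assert np.isfinite(out).all()

    def test_full_bypass_returns_last_position(self, rng):
        block = HadteBlock(
            rng, d_model=32, cfg=HadteConfig(),
            use_residual_eca=False, use_local_mha=False,
            use_global_mha=False, use_tcn=False,
        )
        F = rng.normal(size=(20, 32))
        assert np.array_equal(hadte_forward(F, block), F[-1])

    def test_attention_pair_ablation_keeps_eca_and_tcn_path(self, rng):
        """The no-local+no-global variant wires ECA straight into the TCN."""
        seed_rng = np.random.default_rng(42)
        block = HadteBlock(seed_rng, d_model=8, cfg=HadteConfig(),
                           use_local_mha=False, use_global_mha=False)
        F = rng.normal(size=(10, 8))
        expected = tcn_forward(residual_eca(F, block.eca), block.tcn)
        assert np.abs(hadte_forward(F, block) - expected).max() < 1e-12
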