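"""Block-level behavior: shape contracts, identities, and hand oracles."""

import numpy as np
import pytest

from ievit import autograd as ag
from ievit.autograd import Tensor
from ievit.blocks import (DepthwiseSeparableConv, DSConvSpec, InceptionA,
                          InceptionB, InceptionSpec, MV2Block, MV2Spec,
                          TransformerLayer, ViTBlock, ViTBlockSpec, attention,
                          fold_patches, swish, unfold_patches)


@pytest.fixture
def rng():
    return np.random.default_rng(7)


# ---------------------------------------------------------------------------
# swish
# ---------------------------------------------------------------------------

def test_swish_values():
    assert swish(0.0) == 0.0
    assert np.isclose(swish(1.0), 1.0 / (1.0 + np.exp(-1.0)))
    # saturates to the identity for large positive inputs
    assert abs(swish(20.0) - 20.0) / 20.0 < 1e-6
    out = swish(Tensor(np.array([0.0, 1.0])))
    np.testing.assert_allclose(out.data, [0.0, 1.0 / (1 + np.exp(-1))])


# ---------------------------------------------------------------------------
# depthwise separable convolution
# ---------------------------------------------------------------------------

def test_dsconv_delta_kernel_is_identity(rng):
    spec = DSConvSpec(kernel=3, in_channels=4, out_channels=4)
    op = DepthwiseSeparableConv(spec, rng)
    op.dw.w.data[...] = 0
    op.dw.w.data[1, 1, :, 0] = 1.0          # centered delta per channel
    op.pw.w.data[...] = np.eye(4)[None, None]
    op.pw.b.data[...] = 0
    x = rng.random((1, 8, 8, 4), dtype=np.float32)
    np.testing.assert_allclose(op(Tensor(x)).data, x, atol=1e-6)


def test_dsconv_stride_shape(rng):
    spec = DSConvSpec(kernel=3, in_channels=4, out_channels=6, stride=2)
    op = DepthwiseSeparableConv(spec, rng)
    y = op(Tensor(np.zeros((2, 8, 8, 4), np.float32)))
    assert y.shape == (2, 4, 4, 6)


def _direct_dsconv(x, dw, pw, bias):
    """Brute-force nested-loop reference for same-padding stride-1 dw-sep."""
    K, _, C, A = dw.shape
    H, W = x.shape[:2]
    pad = K // 2
    xp = np.pad(x, ((pad, pad), (pad, pad), (0, 0)))
    mid = np.zeros((H, W, C * A))
    for i in range(H):
        for j in range(W):
            for c in range(C):
                for a in range(A):
                    mid[i, j, c * A + a] = (
                        xp[i:i + K, j:j + K, c] * dw[:, :, c, a]).sum()
    return mid @ pw[0, 0] + bias


def test_dsconv_matches_direct_convolution(rng):
    spec = DSConvSpec(kernel=3, in_channels=2, out_channels=3,
                      depth_multiplier=2)
    op = DepthwiseSeparableConv(spec, rng)
    x = rng.random((5, 5, 2)).astype(np.float32)
    got = op(Tensor(x[None])).data[0]
    want = _direct_dsconv(x.astype(np.float64), op.dw.w.data.astype(np.float64),
                          op.pw.w.data.astype(np.float64), op.pw.b.data)
    np.testing.assert_allclose(got, want, atol=1e-5)


def test_dsconv_constant_input_gives_constant_output(rng):
    spec = DSConvSpec(kernel=3, in_channels=2, out_channels=3)
    op = DepthwiseSeparableConv(spec, rng)
    x = np.full((1, 9, 9, 2), 0.5, np.float32)
    y = op(Tensor(x)).data
    # interior positions see the full kernel: constant per output channel
    interior = y[0, 2:-2, 2:-2, :]
    np.testing.assert_allclose(
        interior, np.broadcast_to(interior[0, 0], interior.shape), atol=1e-6)
    eff = (op.dw.w.data.sum(axis=(0, 1))[:, 0] @ op.pw.w.data[0, 0]) * 0.5 \
        + op.pw.b.data
    np.testing.assert_allclose(interior[0, 0], eff, atol=1e-6)


def test_dsconv_channel_mismatch_raises(rng):
    op = DepthwiseSeparableConv(DSConvSpec(3, 4, 4), rng)
    with pytest.raises(ValueError, match="channels"):
        op(Tensor(np.zeros((1, 4, 4, 3), np.float32)))


# ---------------------------------------------------------------------------
# inception blocks
# ---------------------------------------------------------------------------

def test_inception_table_instances_shape(rng):
    from ievit.model import _DEF_INC_A, _DEF_INC_B
    a = InceptionA(_DEF_INC_A, rng)
    b = InceptionB(_DEF_INC_B, rng)
    x = rng.random((1, 128, 128, 16), dtype=np.float32)
    ya = a(Tensor(x))
    assert ya.shape == (1, 128, 128, 160)
    yb = b(ya)
    assert yb.shape == (1, 128, 128, 192)


def test_inception_width1_concat(rng):
    spec = InceptionSpec(2, 1, 1, 1, 1, 1, 1, 1, kernel=3, pool="max")
    y = InceptionA(spec, rng)(Tensor(np.zeros((1, 4, 4, 2), np.float32)))
    assert y.shape == (1, 4, 4, 4)


def test_inception_param_count_is_sum_of_branch_layers(rng):
    from ievit.accounting import count_params
    spec = InceptionSpec(3, 8, 8, 16, 8, 8, 16, 8, kernel=3, pool="max")
    block = InceptionA(spec, rng)
    per_layer = sum(m.param_count() for m in
                    (block.p1, block.p2a, block.p2b, block.p3a, block.p3b,
                     block.p3c, block.p4))
    assert block.param_count() == per_layer == count_params(spec)


def test_inception_avgpool_branch_preserves_constant(rng):
    spec = InceptionSpec(2, 1, 1, 1, 1, 1, 1, 1, kernel=7, pool="avg")
    block = InceptionB(spec, rng)
    x = Tensor(np.full((1, 6, 6, 2), 0.7, np.float32))
    pooled = block.pool(x)
    np.testing.assert_allclose(pooled.data, 0.7, atol=1e-6)


def test_inception_invalid_width_raises():
    with pytest.raises(ValueError, match="positive"):
        InceptionSpec(2, 0, 1, 1, 1, 1, 1, 1)


# ---------------------------------------------------------------------------
# MV2 block
# ---------------------------------------------------------------------------

def test_mv2_zero_weights_residual_is_identity(rng):
    spec = MV2Spec(24, 24, expansion=2, stride=1)
    block = MV2Block(spec, rng)
    for t in block.parameters():
        t.data[...] = 0
    block.expand.bn.gamma.data[...] = 0     # kill normalization output too
    block.dw_bn.gamma.data[...] = 0
    block.project.bn.gamma.data[...] = 0
    x = rng.random((2, 6, 6, 24), dtype=np.float32)
    np.testing.assert_allclose(block(Tensor(x)).data, x, atol=1e-6)


def test_mv2_stride2_shape(rng):
    block = MV2Block(MV2Spec(16, 24, expansion=2, stride=2), rng)
    y = block(Tensor(np.zeros((1, 128, 128, 16), np.float32)))
    assert y.shape == (1, 64, 64, 24)


def test_mv2_no_residual_when_channels_differ():
    assert not MV2Spec(16, 24, stride=1).residual
    assert not MV2Spec(24, 24, stride=2).residual
    assert MV2Spec(24, 24, stride=1).residual


def test_mv2_param_count_matches_enumeration(rng):
    from ievit.accounting import count_params
    for spec in (MV2Spec(4, 4, expansion=2),
                 MV2Spec(8, 12, expansion=3, stride=2),
                 MV2Spec(16, 16, expansion=2, pre_reduce_from=40),
                 MV2Spec(6, 6, expansion=2, depth_multiplier=2)):
        assert MV2Block(spec, rng).param_count() == count_params(spec)


def test_mv2_wrong_input_channels_raises(rng):
    block = MV2Block(MV2Spec(16, 24), rng)
    with pytest.raises(ValueError, match="channels"):
        block(Tensor(np.zeros((1, 4, 4, 8), np.float32)))


# ---------------------------------------------------------------------------
# attention
# ---------------------------------------------------------------------------

def test_attention_single_token_returns_value(rng):
    q = rng.standard_normal((1, 4))
    k = rng.standard_normal((1, 4))
    v = rng.standard_normal((1, 4))
    np.testing.assert_allclose(attention(q, k, v).data, v, atol=1e-7)


def test_attention_zero_query_averages_values(rng):
    k = rng.standard_normal((5, 3))
    v = rng.standard_normal((5, 3))
    out = attention(np.zeros((5, 3)), k, v).data
    np.testing.assert_allclose(out, np.broadcast_to(v.mean(0), (5, 3)),
                               atol=1e-7)


def test_attention_two_token_hand_computation():
    q = np.array([[1.0], [0.0]])
    k = np.array([[1.0], [0.0]])
    v = np.array([[2.0], [4.0]])
    out = attention(q, k, v).data          # d=1 so the scale is 1
    e = np.e
    row1 = (e * 2 + 4) / (e + 1)
    np.testing.assert_allclose(out, [[row1], [3.0]], atol=1e-12)


def test_attention_rows_convex_combination(rng):
    q = rng.standard_normal((2, 7, 6))
    k = rng.standard_normal((2, 7, 6))
    v = rng.standard_normal((2, 7, 6))
    out = attention(q, k, v).data
    lo = v.min(axis=-2, keepdims=True)
    hi = v.max(axis=-2, keepdims=True)
    assert (out >= lo - 1e-6).all() and (out <= hi + 1e-6).all()


def test_attention_weight_rows_sum_to_one(rng):
    q = Tensor(rng.standard_normal((4, 5)))
    k = Tensor(rng.standard_normal((4, 5)))
    scores = ag.mul(ag.matmul(q, ag.transpose(k, (1, 0))), 1 / np.sqrt(5))
    w = ag.softmax(scores, axis=-1).data
    np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-6)


# ---------------------------------------------------------------------------
# transformer layer
# ---------------------------------------------------------------------------

def _zero_dense(d):
    d.w.data[...] = 0
    if d.b is not None:
        d.b.data[...] = 0


def test_transformer_zero_weights_is_identity(rng):
    spec = ViTBlockSpec(8, 8, embed_dim=8, heads=2, patch_size=2)
    layer = TransformerLayer(spec, rng)
    for dense in (layer.mha.q, layer.mha.k, layer.mha.v, layer.mha.out,
                  layer.fc1, layer.fc2):
        _zero_dense(dense)
    x = rng.standard_normal((1, 4, 6, 8)).astype(np.float32)
    np.testing.assert_allclose(layer(Tensor(x)).data, x, atol=1e-6)


def test_transformer_preserves_shape(rng):
    spec = ViTBlockSpec(48, 80, embed_dim=80, heads=4, patch_size=8)
    layer = TransformerLayer(spec, rng)
    x = rng.standard_normal((1, 1, 1024, 80)).astype(np.float32)
    assert layer(Tensor(x)).shape == (1, 1, 1024, 80)


def _reference_transformer(x, layer, scale):
    """Independent numpy re-implementation of the pre-norm layer."""
    def ln(a, g, b, eps=1e-6):
        mu = a.mean(-1, keepdims=True)
        var = a.var(-1, keepdims=True)
        return g * (a - mu) / np.sqrt(var + eps) + b

    def dense(a, d):
        y = a @ d.w.data
        return y + d.b.data if d.b is not None else y

    h = layer.mha.heads
    x1 = ln(x, layer.ln1.gamma.data, layer.ln1.beta.data)
    q, k, v = dense(x1, layer.mha.q), dense(x1, layer.mha.k), dense(x1, layer.mha.v)
    N, A = q.shape[-2:]
    dk = A // h
    out = np.zeros_like(q)
    for head in range(h):
        sl = slice(head * dk, (head + 1) * dk)
        s = q[..., sl] @ k[..., sl].swapaxes(-1, -2) / scale
        s = np.exp(s - s.max(-1, keepdims=True))
        s /= s.sum(-1, keepdims=True)
        out[..., sl] = s @ v[..., sl]
    x2 = x + dense(out, layer.mha.out)
    x3 = ln(x2, layer.ln2.gamma.data, layer.ln2.beta.data)
    hmid = dense(x3, layer.fc1)
    hmid = hmid / (1 + np.exp(-hmid))
    return x2 + dense(hmid, layer.fc2)


def test_transformer_matches_reference_forward(rng):
    spec = ViTBlockSpec(4, 4, embed_dim=6, heads=2, attn_dim=8, mlp_hidden=10,
                        patch_size=2)
    layer = TransformerLayer(spec, rng)
    for p in layer.parameters():
        p.data[...] = rng.standard_normal(p.shape).astype(np.float32) * 0.3
    x = rng.standard_normal((1, 2, 2, 6)).astype(np.float32)
    want = _reference_transformer(x.astype(np.float64), layer,
                                  np.sqrt(spec.embed_dim))
    np.testing.assert_allclose(layer(Tensor(x)).data, want, atol=1e-5)


def test_heads_must_divide_attn_dim():
    with pytest.raises(ValueError, match="divisible"):
        ViTBlockSpec(8, 8, embed_dim=8, heads=3, attn_dim=8)


# ---------------------------------------------------------------------------
# patch folding
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("hw,patch", [(4, 2), (8, 2), (8, 4), (16, 8),
                                      (32, 8), (16, 16)])
def test_fold_unfold_roundtrip(rng, hw, patch):
    x = rng.standard_normal((2, hw, hw, 3)).astype(np.float32)
    t = unfold_patches(Tensor(x), patch)
    assert t.shape == (2, patch * patch, (hw // patch) ** 2, 3)
    back = fold_patches(t, hw, hw, 3, patch)
    np.testing.assert_array_equal(back.data, x)


def test_unfold_counts():
    x = Tensor(np.zeros((1, 4, 4, 1), np.float32))
    assert unfold_patches(x, 2).shape == (1, 4, 4, 1)   # 4 patches x 4 positions
    x = Tensor(np.zeros((1, 32, 32, 1), np.float32))
    assert unfold_patches(x, 8).shape[2] == 16          # (32/8)^2 patches


def test_unfold_indivisible_raises():
    with pytest.raises(ValueError, match="divisible"):
        unfold_patches(Tensor(np.zeros((1, 6, 6, 1), np.float32)), 4)


# ---------------------------------------------------------------------------
# ViT block
# ---------------------------------------------------------------------------

def test_vit_block_table_shape_contracts(rng):
    from ievit.model import _DEF_VIT_1, _DEF_VIT_2
    b1 = ViTBlock(_DEF_VIT_1, rng)
    y1 = b1(Tensor(np.zeros((1, 32, 32, 48), np.float32)))
    assert y1.shape == (1, 32, 32, 80)
    b2 = ViTBlock(_DEF_VIT_2, rng)
    y2 = b2(Tensor(np.zeros((1, 16, 16, 80), np.float32)))
    assert y2.shape == (1, 16, 16, 96)


def test_vit_block_depth0_degenerates_to_convolutions(rng):
    spec = ViTBlockSpec(6, 10, embed_dim=8, depth=0, heads=2, patch_size=2)
    block = ViTBlock(spec, rng)
    x = rng.random((1, 8, 8, 6), dtype=np.float32)
    got = block(Tensor(x)).data
    y = block.proj(block.local(Tensor(x)))
    y = block.back(y)
    want = block.fuse(ag.concat([Tensor(x), y], axis=-1)).data
    np.testing.assert_allclose(got, want, atol=1e-6)


def test_vit_block_param_count_matches_enumeration(rng):
    from ievit.accounting import count_params
    from ievit.model import _DEF_VIT_1, _DEF_VIT_2
    for spec in (_DEF_VIT_1, _DEF_VIT_2,
                 ViTBlockSpec(6, 10, embed_dim=8, depth=3, heads=2,
                              qkv_bias=False, mlp_bias=False, patch_size=2)):
        assert ViTBlock(spec, rng).param_count() == count_params(spec)
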