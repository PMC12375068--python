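"""Neural building blocks of the inception-enhanced vision transformer.

Every block is a pure, shape-contracted operator on NHWC feature maps:
deterministic given its weights, with "same" padding throughout so spatial
dimensions only change through explicit strides.  The block zoo covers

* Swish and the depthwise separable convolution primitive,
* two inception blocks (InceptionA with 3x3 branches and max pooling,
  InceptionB with 7x7 branches and average pooling),
* the inverted bottleneck (MV2) with expand -> depthwise -> project and an
  identity shortcut whenever the shapes allow it,
* scaled dot-product attention, the pre-norm transformer layer, and the
  MobileViT-style ViT block that folds non-overlapping patches into token
  sequences and back.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import autograd as ag
from .autograd import Tensor, as_tensor
from .layers import (AvgPool2D, BatchNorm2D, Conv2D, ConvBN, Dense,
                     DepthwiseConv2D, LayerNorm, MaxPool2D, Module,
                     SeparableConvBN)

__all__ = [
    "swish", "attention", "unfold_patches", "fold_patches",
    "TensorSpec", "DSConvSpec", "InceptionSpec", "MV2Spec", "ViTBlockSpec",
    "DepthwiseSeparableConv", "InceptionA", "InceptionB", "MV2Block",
    "TransformerLayer", "ViTBlock",
]


def swish(x):
    """The Swish activation x * sigmoid(x), elementwise on scalars or tensors."""
    if isinstance(x, Tensor):
        return ag.swish(x)
    return np.asarray(x) / (1.0 + np.exp(-np.asarray(x)))


def attention(q, k, v, scale: Optional[float] = None):
    """Scaled dot-product attention softmax(QK^T / sqrt(d)) V.

    ``q``, ``k``, ``v`` have shape (..., N, d); by default the scale is the
    square root of the last dimension of ``q``.  Rows of the attention-weight
    matrix form a probability distribution, so each output row is a convex
    combination of the value rows.
    """
    q, k, v = as_tensor(q), as_tensor(k), as_tensor(v)
    if scale is None:
        scale = float(np.sqrt(q.shape[-1]))
    scores = ag.mul(ag.matmul(q, ag.transpose(k, _swap_last(k.ndim))), 1.0 / scale)
    return ag.matmul(ag.softmax(scores, axis=-1), v)


def _swap_last(ndim):
    axes = list(range(ndim))
    axes[-1], axes[-2] = axes[-2], axes[-1]
    return tuple(axes)


# ---------------------------------------------------------------------------
# patch (un)folding
# ---------------------------------------------------------------------------

def unfold_patches(x, patch: int):
    """Partition an (B, H, W, C) map into non-overlapping patch token groups.

    Returns shape (B, patch*patch, P, C) with P = (H/patch) * (W/patch):
    for each of the patch*patch pixel offsets, a sequence of P patch tokens.
    Attention then runs across patches independently per offset.
    """
    x = as_tensor(x)
    B, H, W, C = x.shape
    if H % patch or W % patch:
        raise ValueError(
            f"spatial dims ({H}x{W}) not divisible by patch size {patch}")
    hp, wp = H // patch, W // patch
    y = ag.reshape(x, (B, hp, patch, wp, patch, C))
    y = ag.transpose(y, (0, 2, 4, 1, 3, 5))
    return ag.reshape(y, (B, patch * patch, hp * wp, C))


def fold_patches(tokens, H: int, W: int, C: int, patch: int):
    """Exact inverse of :func:`unfold_patches`."""
    tokens = as_tensor(tokens)
    B = tokens.shape[0]
    hp, wp = H // patch, W // patch
    y = ag.reshape(tokens, (B, patch, patch, hp, wp, C))
    y = ag.transpose(y, (0, 3, 1, 4, 2, 5))
    return ag.reshape(y, (B, H, W, C))


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TensorSpec:
    """Shape contract (height, width, channels) flowing between layers."""
    height: int
    width: int
    channels: int

    def __post_init__(self):
        if min(self.height, self.width, self.channels) < 1:
            raise ValueError("TensorSpec fields must be >= 1")

    def strided(self, stride: int, channels: int) -> "TensorSpec":
        """Shape after a stride-s same-padded layer with a new channel count."""
        return TensorSpec(-(-self.height // stride), -(-self.width // stride),
                          channels)


@dataclass(frozen=True)
class DSConvSpec:
    """Depthwise separable convolution hyperparameters."""
    kernel: int
    in_channels: int
    out_channels: int
    depth_multiplier: int = 1
    stride: int = 1
    use_bias: bool = True


@dataclass(frozen=True)
class InceptionSpec:
    """Branch widths of an inception block.

    Branches: (1) 1x1 conv -> b1; (2) 1x1 -> b2a then KxK separable -> b2b;
    (3) 1x1 -> b3a then two KxK separables -> b3m -> b3b; (4) KxK pooling
    then 1x1 -> b4.  Concatenated output has b1 + b2b + b3b + b4 channels.
    """
    in_channels: int
    b1: int
    b2a: int
    b2b: int
    b3a: int
    b3m: int
    b3b: int
    b4: int
    kernel: int = 3           # 3 for InceptionA, 7 for InceptionB
    pool: str = "max"         # "max" for InceptionA, "avg" for InceptionB

    def __post_init__(self):
        if min(self.b1, self.b2a, self.b2b, self.b3a, self.b3m, self.b3b,
               self.b4) < 1:
            raise ValueError("inception branch widths must be positive")

    @property
    def out_channels(self) -> int:
        return self.b1 + self.b2b + self.b3b + self.b4


@dataclass(frozen=True)
class MV2Spec:
    """Inverted bottleneck hyperparameters.

    ``pre_reduce_from``, when set, inserts a KxK separable reduction from that
    channel count down to ``in_channels`` in front of the bottleneck — the
    channel-flow layout used where the wide inception output (192 channels)
    meets the narrow bottleneck chain (16 channels).
    """
    in_channels: int
    out_channels: int
    expansion: int = 2
    kernel: int = 3
    depth_multiplier: int = 1
    stride: int = 1
    pre_reduce_from: Optional[int] = None

    @property
    def residual(self) -> bool:
        return self.stride == 1 and self.in_channels == self.out_channels


@dataclass(frozen=True)
class ViTBlockSpec:
    """MobileViT-style block hyperparameters.

    ``attn_dim`` is the total width of the query/key/value projections
    (heads x per-head dimension); ``embed_dim`` is the token embedding d.
    The attention logits are scaled by sqrt(embed_dim).
    """
    in_channels: int
    out_channels: int
    embed_dim: int
    depth: int = 2
    heads: int = 4
    attn_dim: Optional[int] = None      # default: 2 * embed_dim
    mlp_hidden: Optional[int] = None    # default: 2 * embed_dim
    qkv_bias: bool = True
    out_bias: bool = True
    mlp_bias: bool = True
    patch_size: int = 8

    def __post_init__(self):
        object.__setattr__(self, "attn_dim",
                           self.attn_dim or 2 * self.embed_dim)
        object.__setattr__(self, "mlp_hidden",
                           self.mlp_hidden or 2 * self.embed_dim)
        if self.attn_dim % self.heads:
            raise ValueError("attn_dim must be divisible by the head count")

    @property
    def mlp_ratio(self) -> float:
        return self.mlp_hidden / self.embed_dim


# ---------------------------------------------------------------------------
# blocks
# ---------------------------------------------------------------------------

class DepthwiseSeparableConv(Module):
    """Per-channel KxK convolution followed by a 1x1 pointwise convolution."""

    def __init__(self, spec: DSConvSpec, rng):
        super().__init__()
        self.spec = spec
        self.dw = DepthwiseConv2D(spec.in_channels, spec.kernel, rng,
                                  spec.stride, spec.depth_multiplier)
        self.pw = Conv2D(spec.in_channels * spec.depth_multiplier,
                         spec.out_channels, 1, rng, 1, bias=spec.use_bias)

    def forward(self, x, training=False):
        if x.shape[-1] != self.spec.in_channels:
            raise ValueError(
                f"expected {self.spec.in_channels} input channels, got {x.shape[-1]}")
        return self.pw(self.dw(x, training), training)


class _Inception(Module):
    def __init__(self, spec: InceptionSpec, rng):
        super().__init__()
        self.spec = spec
        c, K = spec.in_channels, spec.kernel
        self.p1 = ConvBN(c, spec.b1, 1, rng, activation="relu")
        self.p2a = ConvBN(c, spec.b2a, 1, rng, activation="relu")
        self.p2b = SeparableConvBN(spec.b2a, spec.b2b, K, rng, activation="relu")
        self.p3a = ConvBN(c, spec.b3a, 1, rng, activation="relu")
        self.p3b = SeparableConvBN(spec.b3a, spec.b3m, K, rng, activation="relu")
        self.p3c = SeparableConvBN(spec.b3m, spec.b3b, K, rng, activation="relu")
        self.pool = MaxPool2D(3, 1) if spec.pool == "max" else AvgPool2D(3, 1)
        self.p4 = ConvBN(c, spec.b4, 1, rng, activation="relu")

    def forward(self, x, training=False):
        if x.shape[-1] != self.spec.in_channels:
            raise ValueError(
                f"expected {self.spec.in_channels} input channels, got {x.shape[-1]}")
        b1 = self.p1(x, training)
        b2 = self.p2b(self.p2a(x, training), training)
        b3 = self.p3c(self.p3b(self.p3a(x, training), training), training)
        b4 = self.p4(self.pool(x, training), training)
        return ag.concat([b1, b2, b3, b4], axis=-1)


class InceptionA(_Inception):
    """Four-branch inception with 3x3 separable convolutions and max pooling."""

    def __init__(self, spec: InceptionSpec, rng):
        if spec.kernel != 3 or spec.pool != "max":
            raise ValueError("InceptionA uses kernel 3 and max pooling")
        super().__init__(spec, rng)


class InceptionB(_Inception):
    """Four-branch inception with 7x7 separable convolutions and average pooling."""

    def __init__(self, spec: InceptionSpec, rng):
        if spec.kernel != 7 or spec.pool != "avg":
            raise ValueError("InceptionB uses kernel 7 and average pooling")
        super().__init__(spec, rng)


class MV2Block(Module):
    """Inverted bottleneck: 1x1 expand (Swish) -> depthwise (Swish) -> 1x1 project.

    The identity shortcut is applied only when stride is 1 and the input and
    output widths agree; a stride-2 depthwise stage performs downsampling.
    """

    def __init__(self, spec: MV2Spec, rng):
        super().__init__()
        self.spec = spec
        cin, e = spec.in_channels, spec.in_channels * spec.expansion
        if spec.pre_reduce_from is not None:
            # depthwise + BN + pointwise + BN reduction into the bottleneck width
            self.r_dw = DepthwiseConv2D(spec.pre_reduce_from, spec.kernel, rng)
            self.r_dw_bn = BatchNorm2D(spec.pre_reduce_from)
            self.r_pw = ConvBN(spec.pre_reduce_from, cin, 1, rng, activation="swish")
            self.has_reduce = True
        else:
            self.has_reduce = False
        self.expand = ConvBN(cin, e, 1, rng, activation="swish")
        self.dw = DepthwiseConv2D(e, spec.kernel, rng, spec.stride,
                                  spec.depth_multiplier)
        self.dw_bn = BatchNorm2D(e * spec.depth_multiplier)
        self.project = ConvBN(e * spec.depth_multiplier, spec.out_channels, 1, rng)

    def forward(self, x, training=False):
        expected = (self.spec.pre_reduce_from
                    if self.spec.pre_reduce_from is not None
                    else self.spec.in_channels)
        if x.shape[-1] != expected:
            raise ValueError(
                f"expected {expected} input channels, got {x.shape[-1]}")
        if self.has_reduce:
            x = ag.swish(self.r_dw_bn(self.r_dw(x, training), training))
            x = self.r_pw(x, training)
        y = self.expand(x, training)
        y = ag.swish(self.dw_bn(self.dw(y, training), training))
        y = self.project(y, training)
        if self.spec.residual:
            y = ag.add(y, x)
        return y


class MultiHeadAttention(Module):
    """Multi-head scaled dot-product attention over the second-to-last axis.

    Query/key/value projections map d -> attn_dim, split across heads; the
    output projection maps attn_dim back to d.  Logits are scaled by
    sqrt(embed_dim) (the token embedding dimensionality).
    """

    def __init__(self, spec: ViTBlockSpec, rng):
        super().__init__()
        d, a = spec.embed_dim, spec.attn_dim
        self.heads = spec.heads
        self.scale = float(np.sqrt(d))
        self.q = Dense(d, a, rng, bias=spec.qkv_bias)
        self.k = Dense(d, a, rng, bias=spec.qkv_bias)
        self.v = Dense(d, a, rng, bias=spec.qkv_bias)
        self.out = Dense(a, d, rng, bias=spec.out_bias)

    def _split(self, t):
        *lead, N, A = t.shape
        h = self.heads
        t = ag.reshape(t, (*lead, N, h, A // h))
        axes = (*range(len(lead)), len(lead) + 1, len(lead), len(lead) + 2)
        return ag.transpose(t, axes)

    def forward(self, x, training=False):
        q, k, v = self._split(self.q(x)), self._split(self.k(x)), self._split(self.v(x))
        a = attention(q, k, v, scale=self.scale)
        *lead, h, N, dk = a.shape
        axes = (*range(len(lead)), len(lead) + 1, len(lead), len(lead) + 2)
        a = ag.reshape(ag.transpose(a, axes), (*lead, N, h * dk))
        return self.out(a)


class TransformerLayer(Module):
    """Pre-norm transformer: LN -> MHA -> residual, LN -> MLP (Swish) -> residual."""

    def __init__(self, spec: ViTBlockSpec, rng):
        super().__init__()
        d = spec.embed_dim
        self.ln1 = LayerNorm(d)
        self.mha = MultiHeadAttention(spec, rng)
        self.ln2 = LayerNorm(d)
        self.fc1 = Dense(d, spec.mlp_hidden, rng, bias=spec.mlp_bias,
                         activation="swish")
        self.fc2 = Dense(spec.mlp_hidden, d, rng, bias=spec.mlp_bias)

    def forward(self, x, training=False):
        x = ag.add(x, self.mha(self.ln1(x), training))
        return ag.add(x, self.fc2(self.fc1(self.ln2(x))))


class ViTBlock(Module):
    """MobileViT-style global-feature block.

    Local 3x3 convolution into the embedding width, 1x1 projection, patch
    unfolding, a stack of transformer layers, folding back to a map, 1x1
    projection back to the input width, concatenation with the block input,
    and a 3x3 fusion convolution to the output width.  Spatial dimensions are
    preserved and must be divisible by the patch size.
    """

    def __init__(self, spec: ViTBlockSpec, rng):
        super().__init__()
        self.spec = spec
        cin, d = spec.in_channels, spec.embed_dim
        self.local = Conv2D(cin, d, 3, rng, activation="swish")
        self.proj = Conv2D(d, d, 1, rng, activation="swish")
        self.layers = [TransformerLayer(spec, rng) for _ in range(spec.depth)]
        for i, layer in enumerate(self.layers):
            setattr(self, f"layer{i}", layer)
        self.back = Conv2D(d, cin, 1, rng, activation="swish")
        self.fuse = Conv2D(2 * cin, spec.out_channels, 3, rng, activation="swish")

    def forward(self, x, training=False):
        spec = self.spec
        if x.shape[-1] != spec.in_channels:
            raise ValueError(
                f"expected {spec.in_channels} input channels, got {x.shape[-1]}")
        B, H, W, _ = x.shape
        y = self.proj(self.local(x, training), training)
        t = unfold_patches(y, spec.patch_size)
        for layer in self.layers:
            t = layer(t, training)
        y = fold_patches(t, H, W, spec.embed_dim, spec.patch_size)
        y = self.back(y, training)
        y = ag.concat([x, y], axis=-1)
        return self.fuse(y, training)
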