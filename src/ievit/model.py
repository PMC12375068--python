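"""Assembly of the full inception-enhanced vision transformer.

The default configuration reproduces the reference architecture: a stride-2
convolutional stem, InceptionA and InceptionB for multi-kernel local feature
extraction, a chain of inverted bottlenecks interleaved with two
MobileViT-style transformer blocks for global features, then a 1x1
convolution, global average pooling and a softmax dense head.

Block hyperparameters the published description omits (inception branch
widths, bottleneck expansion, transformer depth/widths) default to the values
recovered by :func:`ievit.accounting.solve_config` from the published
per-layer parameter table; the test-suite asserts the search reproduces them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Tuple

import numpy as np

from . import autograd as ag
from .accounting import ConvSpec, LayerSummary
from .blocks import (InceptionA, InceptionB, InceptionSpec, MV2Block, MV2Spec,
                     TensorSpec, ViTBlock, ViTBlockSpec)
from .layers import Conv2D, Dense, Module

__all__ = ["IEViTConfig", "IEViT", "build_ievit", "forward"]

# Hyperparameters recovered from the published per-layer parameter table.
_DEF_STEM = ConvSpec(3, 3, 16, bias=True)
_DEF_INC_A = InceptionSpec(16, b1=40, b2a=48, b2b=40, b3a=56, b3m=24, b3b=40,
                           b4=40, kernel=3, pool="max")
_DEF_INC_B = InceptionSpec(160, b1=32, b2a=80, b2b=64, b3a=48, b3m=48, b3b=48,
                           b4=48, kernel=7, pool="avg")
_DEF_MV2 = (
    MV2Spec(16, 16, expansion=2, stride=1, pre_reduce_from=192),
    MV2Spec(16, 24, expansion=2, stride=2),
    MV2Spec(24, 24, expansion=2, stride=1),
    MV2Spec(24, 48, expansion=2, stride=2),
)
_DEF_VIT_1 = ViTBlockSpec(48, 80, embed_dim=80, depth=2, heads=4,
                          attn_dim=160, mlp_hidden=160)
_DEF_MV2_5 = MV2Spec(80, 80, expansion=2, stride=2)
_DEF_VIT_2 = ViTBlockSpec(80, 96, embed_dim=96, depth=2, heads=4,
                          attn_dim=240, mlp_hidden=216, qkv_bias=False)
_DEF_HEAD = ConvSpec(1, 96, 320, bias=True)


@dataclass(frozen=True)
class IEViTConfig:
    """Full model configuration; defaults reproduce the reference layer table."""
    input: TensorSpec = TensorSpec(256, 256, 3)
    num_classes: int = 5
    patch_size: int = 8
    stem: ConvSpec = _DEF_STEM
    inception_a: InceptionSpec = _DEF_INC_A
    inception_b: InceptionSpec = _DEF_INC_B
    mv2: Tuple[MV2Spec, ...] = _DEF_MV2
    vit_1: ViTBlockSpec = _DEF_VIT_1
    mv2_5: MV2Spec = _DEF_MV2_5
    vit_2: ViTBlockSpec = _DEF_VIT_2
    head: ConvSpec = _DEF_HEAD
    seed: int = 0

    def __post_init__(self):
        if self.patch_size not in (2, 4, 8, 16):
            raise ValueError("patch_size must be one of 2, 4, 8, 16")
        if self.num_classes < 2:
            raise ValueError("num_classes must be at least 2")

    def with_patch_size(self, n: int) -> "IEViTConfig":
        return replace(self, patch_size=n)


class IEViT(Module):
    """The assembled classifier.  Use :func:`build_ievit` to construct one."""

    def __init__(self, config: IEViTConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config

        self.stem = Conv2D(c.input.channels, c.stem.out_channels, c.stem.kernel,
                           rng, stride=2, bias=c.stem.bias, activation="relu")
        self.inception_a = InceptionA(c.inception_a, rng)
        self.inception_b = InceptionB(c.inception_b, rng)
        self.mv2_blocks = [MV2Block(s, rng) for s in c.mv2]
        for i, m in enumerate(self.mv2_blocks):
            setattr(self, f"mv2_{i + 1}", m)
        self.vit_1 = ViTBlock(replace(c.vit_1, patch_size=c.patch_size), rng)
        self.mv2_5 = MV2Block(c.mv2_5, rng)
        self.vit_2 = ViTBlock(replace(c.vit_2, patch_size=c.patch_size), rng)
        self.head = Conv2D(c.head.in_channels, c.head.out_channels,
                           c.head.kernel, rng, bias=c.head.bias,
                           activation="relu")
        self.dense = Dense(c.head.out_channels, c.num_classes, rng)

        self._layer_list = (
            [("conv_stem", self.stem), ("inception_a", self.inception_a),
             ("inception_b", self.inception_b)]
            + [(f"mv2_{i + 1}", m) for i, m in enumerate(self.mv2_blocks)]
            + [("vit_1", self.vit_1), ("mv2_5", self.mv2_5),
               ("vit_2", self.vit_2), ("conv_head", self.head)])
        self._shapes = self._check_shapes()

    # -- shape chain ---------------------------------------------------------
    def _check_shapes(self) -> List[Tuple[str, TensorSpec]]:
        c = self.config
        shapes = [("input", c.input)]
        cur = c.input

        def advance(name, stride, out_c, in_c, patch=None):
            nonlocal cur
            if cur.channels != in_c:
                raise ValueError(
                    f"shape chain broken at {name!r}: expected {in_c} input "
                    f"channels, previous layer produces {cur.channels}")
            if patch and (cur.height % patch or cur.width % patch):
                raise ValueError(
                    f"shape chain broken at {name!r}: {cur.height}x{cur.width} "
                    f"map not divisible by patch size {patch}")
            cur = cur.strided(stride, out_c)
            shapes.append((name, cur))

        advance("conv_stem", 2, c.stem.out_channels, c.input.channels)
        advance("inception_a", 1, c.inception_a.out_channels,
                c.inception_a.in_channels)
        advance("inception_b", 1, c.inception_b.out_channels,
                c.inception_b.in_channels)
        for i, s in enumerate(c.mv2):
            cin = s.pre_reduce_from if s.pre_reduce_from else s.in_channels
            advance(f"mv2_{i + 1}", s.stride, s.out_channels, cin)
        advance("vit_1", 1, c.vit_1.out_channels, c.vit_1.in_channels,
                patch=c.patch_size)
        advance("mv2_5", c.mv2_5.stride, c.mv2_5.out_channels,
                c.mv2_5.in_channels)
        advance("vit_2", 1, c.vit_2.out_channels, c.vit_2.in_channels,
                patch=c.patch_size)
        advance("conv_head", 1, c.head.out_channels, c.head.in_channels)
        shapes.append(("gap", TensorSpec(1, 1, c.head.out_channels)))
        shapes.append(("dense", TensorSpec(1, 1, c.num_classes)))
        return shapes

    def summary_rows(self) -> List[LayerSummary]:
        counts = {name: mod.param_count() for name, mod in self._layer_list}
        counts["dense"] = self.dense.param_count()
        counts["input"] = counts["gap"] = 0
        return [LayerSummary(name, spec, counts[name])
                for name, spec in self._shapes]

    # -- forward -------------------------------------------------------------
    def features(self, x, training: bool = False):
        """Feature map entering global average pooling, shape (B, h, w, 320)."""
        x = ag.as_tensor(np.asarray(x, dtype=np.float32))
        if x.ndim == 3:
            x = ag.reshape(x, (1, *x.shape))
        expect = self.config.input
        if x.shape[1:] != (expect.height, expect.width, expect.channels):
            raise ValueError(
                f"input shape {x.shape[1:]} does not match configured "
                f"{(expect.height, expect.width, expect.channels)}")
        y = self.stem(x, training)
        y = self.inception_a(y, training)
        y = self.inception_b(y, training)
        for m in self.mv2_blocks:
            y = m(y, training)
        y = self.vit_1(y, training)
        y = self.mv2_5(y, training)
        y = self.vit_2(y, training)
        return self.head(y, training)

    def logits_from_features(self, feats, training: bool = False):
        return self.dense(ag.global_avg_pool(feats), training)

    def logits(self, x, training: bool = False):
        return self.logits_from_features(self.features(x, training), training)

    def forward(self, x, training: bool = False):
        """Class-probability matrix: one softmax row per input image."""
        return ag.softmax(self.logits(x, training), axis=-1)

    # -- persistence ---------------------------------------------------------
    def save_weights(self, path):
        np.savez(path, **self.state())

    def load_weights(self, path):
        with np.load(path) as arrays:
            self.load_state(dict(arrays))


def build_ievit(config: Optional[IEViTConfig] = None, **overrides) -> IEViT:
    """Build an IEViT; raises a descriptive error on a broken shape chain."""
    if config is None:
        config = IEViTConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    return IEViT(config)


def forward(model: IEViT, batch) -> np.ndarray:
    """Inference-mode class probabilities as a plain numpy array."""
    return model.forward(batch, training=False).data
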