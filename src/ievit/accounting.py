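"""Analytic cost and parameter bookkeeping.

Two independent routes exist for every count: the closed-form formulas here
and brute-force enumeration of a block's weight arrays
(:meth:`ievit.layers.Module.param_count`); the test-suite asserts they agree.

The module also implements the constraint search (:func:`solve_config`) that
recovers unprinted block hyperparameters — inception branch widths, the
bottleneck expansion factor, transformer depth and widths — from a published
per-layer parameter table.  The published table of the reference architecture
ships as :data:`PUBLISHED_LAYER_TABLE`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

from .blocks import (DSConvSpec, InceptionSpec, MV2Spec, TensorSpec,
                     ViTBlockSpec)

__all__ = [
    "CostParams", "LayerSummary", "SearchSpace", "ConvSpec", "DenseSpec",
    "dsconv_cost_eq1", "standard_conv_cost_eq2", "count_params",
    "summarize_model", "solve_config", "PUBLISHED_LAYER_TABLE",
    "format_summary",
]


# ---------------------------------------------------------------------------
# computation-cost calculators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CostParams:
    """Symbols of the separable/standard convolution cost formulas.

    d_f: feature-map side length; d_k: kernel side; m: input channels;
    n: output channels (number of filters).
    """
    d_f: int
    d_k: int
    m: int
    n: int

    def __post_init__(self):
        if min(self.d_f, self.d_k, self.m) < 1 or self.n < 0:
            raise ValueError("cost parameters must be positive integers")


def dsconv_cost_eq1(p: CostParams, form: str = "printed") -> int:
    """Depthwise-separable convolution cost.

    ``form="printed"`` evaluates D_K^2 M D_F^2 + M N D_K^2 — the expression
    as published.  ``form="standard"`` evaluates the usual multiply-accumulate
    form D_K^2 M D_F^2 + M N D_F^2, whose second term counts the pointwise
    convolution over the feature map.  Both are provided because the printed
    second term uses the kernel area where the standard formula has the
    feature-map area; neither is assumed intended.
    """
    dw = p.d_k ** 2 * p.m * p.d_f ** 2
    if form == "printed":
        return dw + p.m * p.n * p.d_k ** 2
    if form == "standard":
        return dw + p.m * p.n * p.d_f ** 2
    raise ValueError("form must be 'printed' or 'standard'")


def standard_conv_cost_eq2(p: CostParams) -> int:
    """Standard convolution cost D_K^2 M N D_F^2."""
    return p.d_k ** 2 * p.m * p.n * p.d_f ** 2


# ---------------------------------------------------------------------------
# parameter counting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConvSpec:
    """Plain convolution layer for counting: bias XOR batch-norm (4/channel)."""
    kernel: int
    in_channels: int
    out_channels: int
    bias: bool = True
    bn: bool = False


@dataclass(frozen=True)
class DenseSpec:
    in_features: int
    out_features: int
    bias: bool = True


def _conv(k, m, n, bias=False, bn=False):
    return k * k * m * n + (n if bias else 0) + (4 * n if bn else 0)


def _sep_bn(k, m, n, alpha=1):
    # framework separable convolution with batch-norm in place of the bias
    return k * k * m * alpha + m * alpha * n + 4 * n


def count_params(spec) -> int:
    """Exact parameter count of a layer/block spec under the shipped convention.

    Plain convolutions and dense layers carry biases; blocks normalize with
    batch normalization counted at 4 values per channel (scale, offset and
    the two running statistics) on bias-free convolutions; transformer layer
    normalization contributes 2 values per embedding dimension.
    """
    if isinstance(spec, ConvSpec):
        return _conv(spec.kernel, spec.in_channels, spec.out_channels,
                     spec.bias, spec.bn)
    if isinstance(spec, DenseSpec):
        return (spec.in_features * spec.out_features
                + (spec.out_features if spec.bias else 0))
    if isinstance(spec, DSConvSpec):
        a = spec.depth_multiplier
        return (spec.kernel ** 2 * spec.in_channels * a
                + spec.in_channels * a * spec.out_channels
                + (spec.out_channels if spec.use_bias else 0))
    if isinstance(spec, InceptionSpec):
        k, c = spec.kernel, spec.in_channels
        return (_conv(1, c, spec.b1, bn=True)
                + _conv(1, c, spec.b2a, bn=True) + _sep_bn(k, spec.b2a, spec.b2b)
                + _conv(1, c, spec.b3a, bn=True) + _sep_bn(k, spec.b3a, spec.b3m)
                + _sep_bn(k, spec.b3m, spec.b3b)
                + _conv(1, c, spec.b4, bn=True))
    if isinstance(spec, MV2Spec):
        c, t, a, k = (spec.in_channels, spec.expansion,
                      spec.depth_multiplier, spec.kernel)
        e = c * t
        p = (_conv(1, c, e, bn=True)                     # expand
             + k * k * e * a + 4 * e * a                 # depthwise + BN
             + _conv(1, e * a, spec.out_channels, bn=True))  # project
        if spec.pre_reduce_from is not None:
            r = spec.pre_reduce_from
            p += k * k * r + 4 * r + _conv(1, r, c, bn=True)
        return p
    if isinstance(spec, ViTBlockSpec):
        c, d, o = spec.in_channels, spec.embed_dim, spec.out_channels
        a, h = spec.attn_dim, spec.mlp_hidden
        qb = a if spec.qkv_bias else 0
        ob = d if spec.out_bias else 0
        mb = (h + d) if spec.mlp_bias else 0
        per_layer = (2 * 2 * d                     # two layer norms
                     + 3 * (d * a + qb)            # q, k, v projections
                     + a * d + ob                  # output projection
                     + d * h + h * d + mb)         # MLP
        return (_conv(3, c, d, bias=True) + _conv(1, d, d, bias=True)
                + spec.depth * per_layer
                + _conv(1, d, c, bias=True) + _conv(3, 2 * c, o, bias=True))
    raise TypeError(f"cannot count parameters of {type(spec).__name__}")


# ---------------------------------------------------------------------------
# model summary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayerSummary:
    name: str
    output: TensorSpec
    params: int


def summarize_model(model, include_input: bool = False) -> List[LayerSummary]:
    """One row per top-level layer, parameters counted by weight enumeration."""
    rows = list(model.summary_rows())
    if not include_input:
        rows = [r for r in rows if r.name != "input"]
    return rows


def summary_total(rows: Sequence[LayerSummary]) -> int:
    return sum(r.params for r in rows)


def format_summary(rows: Sequence[LayerSummary]) -> str:
    """Tab-separated table mirroring the published layer/parameter columns."""
    lines = ["layer\toutput\tparams"]
    for r in rows:
        o = r.output
        lines.append(f"{r.name}\t{o.height}x{o.width}x{o.channels}\t{r.params}")
    lines.append(f"total\t-\t{summary_total(rows)}")
    return "\n".join(lines)


#: Published per-layer table of the reference 5-class model at 256x256 input:
#: (row name, output height, width, channels, parameter count).
PUBLISHED_LAYER_TABLE = [
    ("conv_stem", 128, 128, 16, 448),
    ("inception_a", 128, 128, 160, 9472),
    ("inception_b", 128, 128, 192, 53104),
    ("mv2_1", 128, 128, 16, 7264),
    ("mv2_2", 64, 64, 24, 1920),
    ("mv2_3", 64, 64, 24, 3216),
    ("mv2_4", 32, 32, 48, 4464),
    ("vit_1", 32, 32, 80, 270048),
    ("mv2_5", 16, 16, 80, 28640),
    ("vit_2", 16, 16, 96, 493472),
    ("conv_head", 16, 16, 320, 31040),
    ("gap", 1, 1, 320, 0),
    ("dense", 1, 1, 5, 1605),
]

PUBLISHED_TOTAL = 904_693


# ---------------------------------------------------------------------------
# configuration search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SearchSpace:
    """Finite candidate space for the hyperparameters the printed table omits.

    Channel widths are searched in multiples of ``width_step`` (every printed
    channel count is a multiple of 8).
    """
    width_step: int = 8
    stem_kernels: tuple = (1, 3, 5, 7)
    expansions: tuple = (1, 2, 3, 4, 5, 6)
    reduce_widths: tuple = tuple(range(8, 65, 8))
    vit_depths: tuple = tuple(range(1, 9))
    attn_width_max_ratio: int = 4
    mlp_hidden_max_ratio: int = 4


@dataclass
class RowMatch:
    name: str
    target: int
    achieved: int
    spec: object

    @property
    def matched(self) -> bool:
        return self.target == self.achieved

    @property
    def residual(self) -> int:
        return self.achieved - self.target


@dataclass
class SolvedConfig:
    """Result of :func:`solve_config`: block specs plus a per-row match report."""
    stem: ConvSpec
    inception_a: InceptionSpec
    inception_b: InceptionSpec
    mv2: List[MV2Spec]
    vit: List[ViTBlockSpec]
    head: ConvSpec
    dense: DenseSpec
    report: List[RowMatch] = field(default_factory=list)

    @property
    def all_matched(self) -> bool:
        return all(r.matched for r in self.report)

    def report_lines(self) -> str:
        """Machine-readable run report (tab-separated)."""
        lines = ["row\ttarget\tachieved\tresidual\tmatched"]
        for r in self.report:
            lines.append(f"{r.name}\t{r.target}\t{r.achieved}\t"
                         f"{r.residual}\t{str(r.matched).lower()}")
        return "\n".join(lines)


def _solve_conv(target, cin, cout, kernels):
    """Unique plain-conv layout (kernel, bias/bn) matching a printed count."""
    best = None
    for k in kernels:
        for bias, bn in ((True, False), (False, True), (False, False)):
            spec = ConvSpec(k, cin, cout, bias, bn)
            got = count_params(spec)
            if got == target:
                return spec, got
            if best is None or abs(got - target) < abs(best[1] - target):
                best = (spec, got)
    return best


def _solve_inception(target, cin, out_sum, kernel, pool, step, max_w=None):
    """Exact branch widths for an inception block; balanced-width tie-break."""
    max_w = max_w or out_sum
    widths = range(step, max_w + 1, step)
    k = kernel
    # decompose: total = f1(b1) + f4(b4) + g2(b2a,b2b) + g3(b3a,b3m,b3b)
    f1 = {w: _conv(1, cin, w, bn=True) for w in widths}
    g2 = {}   # b2b -> list of (cost, b2a)
    for b2b in widths:
        g2[b2b] = [(_conv(1, cin, b2a, bn=True) + _sep_bn(k, b2a, b2b), b2a)
                   for b2a in widths]
    g3 = {}   # b3b -> dict cost -> list of (b3a, b3m)
    for b3b in widths:
        d = {}
        for b3a in widths:
            head = _conv(1, cin, b3a, bn=True)
            for b3m in widths:
                c = head + _sep_bn(k, b3a, b3m) + _sep_bn(k, b3m, b3b)
                d.setdefault(c, []).append((b3a, b3m))
        g3[b3b] = d
    sols = []
    for b1 in widths:
        for b2b in widths:
            for b3b in widths:
                b4 = out_sum - b1 - b2b - b3b
                if b4 < step or b4 % step:
                    continue
                base = f1[b1] + _conv(1, cin, b4, bn=True)
                for c2, b2a in g2[b2b]:
                    rem = target - base - c2
                    if rem <= 0:
                        continue
                    for b3a, b3m in g3[b3b].get(rem, ()):
                        sols.append((b1, b2a, b2b, b3a, b3m, b3b, b4))
    eq = out_sum // 4

    def key(w):
        return (sum(abs(x - eq) for x in w), w)

    if not sols:
        return None
    w = min(sols, key=key)
    return InceptionSpec(cin, *w, kernel=kernel, pool=pool)


def _solve_mv2(target, cin, cout, stride, space: SearchSpace,
               reduce_from=None):
    """Expansion factor (and optional reduction layout) matching a printed count."""
    cands = []
    if reduce_from is None:
        for t in space.expansions:
            spec = MV2Spec(cin, cout, t, stride=stride)
            cands.append((spec, count_params(spec)))
    else:
        for r in space.reduce_widths:
            for t in space.expansions:
                spec = MV2Spec(r, cout, t, stride=stride,
                               pre_reduce_from=reduce_from)
                cands.append((spec, count_params(spec)))
    exact = [c for c in cands if c[1] == target]
    if exact:
        # prefer the chain's common expansion, then narrower widths
        return min(exact, key=lambda c: (abs(c[0].expansion - 2),
                                         c[0].in_channels))
    return min(cands, key=lambda c: (abs(c[1] - target), c[0].expansion))


def _solve_vit(target, cin, cout, d, patch, heads, space: SearchSpace):
    """Depth, attention width, MLP width and bias toggles matching a count.

    Structural validity: the output projection is always present (it returns
    the attention output to the embedding width, required for the residual
    connection whenever attn_dim differs from the embedding dimension).
    """
    step = space.width_step
    sols = []
    for depth in space.vit_depths:
        for qkv_bias in (True, False):
            for out_bias in (True, False):
                for mlp_bias in (True, False):
                    for a in range(step, space.attn_width_max_ratio * d + 1, step):
                        if a % heads:
                            continue
                        for h in range(step,
                                       space.mlp_hidden_max_ratio * d + 1, step):
                            spec = ViTBlockSpec(
                                cin, cout, d, depth=depth, heads=heads,
                                attn_dim=a, mlp_hidden=h, qkv_bias=qkv_bias,
                                out_bias=out_bias, mlp_bias=mlp_bias,
                                patch_size=patch)
                            sols.append((spec, count_params(spec)))
    exact = [s for s in sols if s[1] == target]

    def key(item):
        s = item[0]
        return (abs(s.attn_dim - 2 * d) + abs(s.mlp_hidden - 2 * d),
                (not s.qkv_bias) + (not s.out_bias) + (not s.mlp_bias),
                s.depth, s.attn_dim, s.mlp_hidden)

    pool = exact if exact else sols
    best = min(pool, key=lambda item: ((0 if exact else abs(item[1] - target)),)
               + key(item))
    return best


def solve_config(search: SearchSpace = None,
                 targets: Optional[Sequence[tuple]] = None,
                 num_classes: Optional[int] = None,
                 patch_size: int = 8,
                 heads: int = 4) -> SolvedConfig:
    """Recover a full model configuration from a printed per-layer table.

    ``targets`` rows are (name, out_h, out_w, out_c, params) in architecture
    order, defaulting to :data:`PUBLISHED_LAYER_TABLE`.  Rows a search cannot
    match exactly are reported with the closest configuration and residual;
    the returned configuration is the closest-total one.  Deterministic given
    the search space: ties break toward balanced branch widths, the chain's
    common expansion factor, and transformer widths nearest twice the
    embedding dimension.
    """
    search = search or SearchSpace()
    if targets is None:
        targets = PUBLISHED_LAYER_TABLE
    if not targets:
        raise ValueError("empty target table")
    rows = {name: (c, p) for name, _h, _w, c, p in targets}
    report = []

    def record(name, target, spec, achieved):
        report.append(RowMatch(name, target, achieved, spec))
        return spec

    stem_c, stem_p = rows["conv_stem"]
    stem, got = _solve_conv(stem_p, 3, stem_c, search.stem_kernels)
    record("conv_stem", stem_p, stem, got)

    ia_c, ia_p = rows["inception_a"]
    inc_a = _solve_inception(ia_p, stem_c, ia_c, 3, "max", search.width_step)
    if inc_a is None:
        raise ValueError("no inception-A widths found in the search space")
    record("inception_a", ia_p, inc_a, count_params(inc_a))

    ib_c, ib_p = rows["inception_b"]
    inc_b = _solve_inception(ib_p, ia_c, ib_c, 7, "avg", search.width_step)
    if inc_b is None:
        raise ValueError("no inception-B widths found in the search space")
    record("inception_b", ib_p, inc_b, count_params(inc_b))

    table = list(targets)
    sizes = {name: h for name, h, _w, _c, _p in table}
    order = [n for n, *_ in table]
    mv2 = []
    prev_c, prev_h = ib_c, sizes["inception_b"]
    for name in order:
        if not name.startswith("mv2"):
            if name.startswith("vit"):
                prev_c, prev_h = rows[name][0], sizes[name]
            continue
        out_c, p = rows[name]
        stride = max(1, prev_h // sizes[name])
        # prefer the plain bottleneck; fall back to the separable-reduction
        # layout where the printed count demands a narrower internal width
        spec, got = _solve_mv2(p, prev_c, out_c, stride, search)
        if got != p:
            rspec, rgot = _solve_mv2(p, None, out_c, stride, search,
                                     reduce_from=prev_c)
            if abs(rgot - p) < abs(got - p):
                spec, got = rspec, rgot
        record(name, p, spec, got)
        mv2.append(spec)
        prev_c, prev_h = out_c, sizes[name]

    vits = []
    vit_ins = {"vit_1": (rows["mv2_4"][0], rows["vit_1"][0]),
               "vit_2": (rows["mv2_5"][0], rows["vit_2"][0])}
    for name in ("vit_1", "vit_2"):
        cin, d = vit_ins[name]
        out_c, p = rows[name]
        spec, got = _solve_vit(p, cin, out_c, d, patch_size, heads, search)
        record(name, p, spec, got)
        vits.append(spec)

    head_c, head_p = rows["conv_head"]
    head, got = _solve_conv(head_p, rows["vit_2"][0], head_c, (1, 3))
    record("conv_head", head_p, head, got)

    dense_target = rows["dense"][1]
    if num_classes is None:
        # infer the class count the printed dense row implies
        num_classes = max(1, round(dense_target / (head_c + 1)))
    dense = DenseSpec(head_c, num_classes)
    record("dense", dense_target, dense, count_params(dense))

    return SolvedConfig(stem=stem, inception_a=inc_a, inception_b=inc_b,
                        mv2=mv2, vit=vits, head=head, dense=dense,
                        report=report)
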