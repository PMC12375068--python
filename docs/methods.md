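# Methods

## Model

The classifier is a hybrid of convolutional local-feature extractors and
transformer global-feature extractors operating on NHWC float32 maps with
"same" padding throughout, so spatial size changes only through explicit
stride-2 stages (the stem and three of the inverted bottlenecks; output size
is the ceiling of input/stride). All blocks are deterministic at inference:
there are no stochastic layers, and batch normalization uses running
statistics in inference mode, so predictions are batch-independent.

Activations follow the convention of the architecture family: ReLU in the
stem and inception convolutions, Swish (x·σ(x)) in the inverted bottlenecks
and transformer blocks.

### Parameter-count convention

Parameter counts enumerate every per-layer array: weights, biases, and for
batch normalization the scale, offset *and* the two running statistics
(4 values per channel) — the "total params" convention of common framework
summaries. Two layer families coexist:

* plain convolutions and dense layers: weight + bias, no normalization
  (the stem 3×3×3×16+16 = 448, the head 1×1 96→320 = 31 040, the dense
  320·5+5 = 1 605 are exact only under this convention);
* block-internal convolutions (inception branches, MV2 stages): bias-free
  convolution + batch normalization at 4 values/channel (the MV2 rows
  1 920 / 3 216 / 4 464 / 28 640 are exact only under this convention, with
  expansion t=2, kernel 3, depth multiplier 1).

Transformer layer normalization contributes 2 values per embedding
dimension. Every closed-form count in `accounting.count_params` is checked
in the test-suite against brute-force enumeration of the real weight arrays
of the corresponding block.

### Recovered hyperparameters

A published layer table fixes each block's input/output shape and parameter
count but not its internals. `solve_config` searches a finite space — widths
in multiples of 8 (every printed channel count is a multiple of 8), expansion
factors 1–6, transformer depth 1–8, attention width up to 4d, MLP width up to
4d, per-sublayer bias toggles — and ships the exact match chosen by a
deterministic tie-break: most balanced inception branch widths; the chain's
common expansion factor; transformer widths nearest twice the embedding
dimension with biases preferred on. Structural validity is enforced during
the search (the attention output projection is always present, since the
residual connection requires the attention output back at the embedding
width). The result for the default model:

* InceptionA (16→160): branches 40 | 48→40 | 56→24→40 | pool→40 (9 472);
* InceptionB (160→192): branches 32 | 80→64 | 48→48→48 | pool→48 (53 104);
* first MV2 row (192→16, 7 264): a depthwise-separable reduction
  (depthwise 3×3 + BN, pointwise 192→16 + BN; 5 632) followed by a t=2
  bottleneck 16→16 (1 632) — the only layout in the space that is exact;
* ViT block 1 (48→80, d=80): depth 2, attention width 160 (= 2d, 4 heads),
  MLP hidden 160, all biases on (270 048) — the canonical configuration of
  this block family;
* ViT block 2 (80→96, d=96): depth 2, attention width 240 (4 heads × 60),
  MLP hidden 216, query/key/value biases off (493 472). No configuration
  with the canonical 2d widths matches this row; the shipped values are the
  exact match closest to them under the tie-break, and the machine-readable
  report from `solve_config` records the match status of every row.

With these values all thirteen rows and the 904 693 total are exact. Rows
that no searched configuration matches exactly are reported with the closest
count and its residual, and the closest-total configuration is shipped.

### Attention details

The standalone `attention(Q, K, V)` operator computes softmax(QKᵀ/s)·V with
s = √d for d the last dimension of Q; rows of the weight matrix are
probability distributions, so each output row is a convex combination of
value rows. Inside the transformer the projections map d → attention width
(split across 4 heads) and the logits are scaled by √d of the full embedding
dimension, with the per-head dimension being attention width / heads. Patch
attention uses the MobileViT arrangement: a feature map unfolds into
(n², P, d) token groups — for each of the n² pixel offsets, a sequence of
the P patches — and attention runs across patches per offset; folding is the
exact inverse, and indivisible spatial dimensions raise an error rather than
silently padding (all default maps are divisible for n ∈ {2, 4, 8, 16}).

## Numerical engine

No external deep-learning framework is used: the package includes a
tape-based reverse-mode autodiff engine on numpy (`ievit.autograd`).
Convolutions use a shift-and-accumulate decomposition (one C_in×C_out matmul
per kernel offset) whose backward pass is exact and memory-proportional to
the feature map; gradients of every primitive are verified against central
finite differences in float64. Average pooling normalizes edge windows by
the number of valid cells, so a constant input yields a constant output.
Max pooling pads with −∞ and routes gradients to the argmax. Cross-entropy
is computed from logits via a fused log-softmax for stability.

Weight initialization is seedable: fan-out-scaled normal for convolutions,
truncated normal (σ = 0.02, resampled beyond 2σ) for dense/transformer
weights, zeros for biases, ones/zeros for normalization scales/offsets.
Weights serialize to a named-tensor `.npz` archive; run configurations
serialize to YAML.

## Training pipeline

Defaults reproduce the reference protocol: Adam with learning rate 0.001,
batch size 32, categorical cross-entropy on the softmax head, stratified
80/20 train/validation split (the splitting scheme is not stated in the
reference description; stratified holdout is the package's choice). Optional
label smoothing is exposed (default 0). Seven optimizers are available
(SGD, Adam, RMSProp, Adamax, Adadelta, Nadam, Ftrl) with standard framework
default hyperparameters; FTRL's closed-form weight update is guarded against
float32 underflow of the squared-gradient accumulator. Preprocessing is
pixel scaling to [0, 1] only; no dataset-statistics normalization and no
augmentation by default. The split, initialization and batch order all
derive from the run seed, so identical configurations reproduce identical
curves in a fixed numerical environment.

Desk-scale experiments run the architecture at reduced input resolution
(32×32 with patch size 2 for the learning smoke test: the transformer maps
are then 4×4 and 2×2, which admit patch 2), keeping the full layer sequence
and channel widths. At this size, ten epochs over 240 training images take
on the order of a minute on one CPU core. Full 256×256 inference runs in
seconds per image.

## Synthetic data

The generator emulates the *structure* of leaf-disease photographs: a green
elliptical leaf silhouette with a pointed tip, central and side veins, and
smooth-edged class-conditional lesions (brown necrotic spots, dense orange
rust dots, irregular blight blotches rendered as short random walks of
overlapping disks, and mosaic-like discoloration via an additive color
shift). A clutter level in [0, 1] blends smooth random background texture
and debris blobs, emulating in-field images with complex backgrounds; at
clutter 0 the background is a flat soil tone and the healthy class has the
highest mean green intensity by construction, so a nearest-class-mean color
classifier already beats chance — the classes are learnable at desk scale by
design. An images-per-class vector emulates class imbalance.

What the generator does **not** emulate: real lesion biology and texture,
illumination variation, occlusion, multiple leaves per frame, or
inter-image correlation. Passing the desk-scale learning test therefore
shows that the architecture, gradients and training loop function end to
end and can fit visually separable classes; it does not predict accuracy on
real crop datasets.

Identical spec and seed produce byte-identical PNGs, making generated
datasets usable as reproducible test fixtures.

## Known limitations

* CPU-only numpy execution: full-resolution training is impractical; the
  package targets architectural analysis, desk-scale training and audit.
* The parameter table underdetermines the inception branch widths and parts
  of the transformer configuration; the shipped values are the deterministic
  tie-break choice among exact matches, not ground truth.
* The computation-cost calculator implements both the as-printed separable
  cost form (whose second term uses the kernel area) and the standard
  multiply-accumulate form (feature-map area); neither is assumed intended,
  and no FLOPs figure is validated against external totals since counting
  conventions vary.
* The separable-vs-standard cost inequality holds when 1/N + 1/K² ≤ 1
  (true for every kernel/filter pair used here); it fails for 1×1 kernels
  or a single filter, so the property is asserted on that domain.
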