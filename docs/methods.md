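# Methods

This note documents the model implemented by `cgmunet`, the choices made
where the design space was genuinely open, the synthetic data the tests run
on, and what the tests do and do not establish.

## Network

### Multi-axis, multi-window MLP (MsM)

`MsMBlock` mixes a feature map spatially with dense layers along fixed-size
axes.  Pipeline: LayerNorm over channels → dense projection (width
multiplier `hidden_ratio`, default 1) → GELU → split into four equal channel
heads → per-head mixing → channel concatenation → dense projection →
dropout.

The four heads, for window base `b` (default 2):

| head | partition | mixed axis | interaction |
|------|-----------|-----------|-------------|
| local 1 | b×b windows | b² window positions | dense, short range |
| local 2 | 2b×2b windows | 4b² window positions | dense, mid range |
| global 1 | b×b arrangement of (H/b)×(W/b) cells | b² cells | dilated lattice, stride (H/b, W/b) |
| global 2 | 2b×2b arrangement of cells | 4b² cells | dilated lattice, stride (H/2b, W/2b) |

`block_partition(x, w)` tiles the map into row-major w×w windows;
`grid_partition(x, g)` is the same partition with cell-sized windows
followed by swapping the two spatial axes, so its tensor is
(within-cell offsets) × (g² cells) × channels and fixing an offset selects
one pixel per cell.  Both are pure rearrangements with exact inverses
(property-tested bit-identically).  The mixing axis always has length b² or
4b², so the parameterization is independent of H and W: the block accepts
any input with H, W divisible by 2b, and non-divisible inputs are rejected
rather than padded (padding would break the exact partition algebra; a
reflect-pad-and-crop convenience wrapper exists in the evaluation path
instead).

Each head's mixer is a single dense layer along the mixing axis with an
internal residual, `t + GELU(Dense(t))` — the minimal structure that mixes
the axis while letting a head start near identity.  The union of the four
heads' supports is the block's receptive field; `msm_receptive_mask`
computes it combinatorially, and the test suite confirms it equals the
numerical Jacobian support on every pixel of an 8×8×4 input.

### MLP cross-gating (MCG)

Two convolutional streams U₁, V₁ are each normalized, projected and
GELU-activated; a *shared* MsM operator is applied to both; each stream is
then multiplied elementwise by the MsM transform of the *other* stream,
projected, dropped out and added residually to its raw input; the block
returns the sum of the two streams.  The two streams have independent
normalization/projection weights (exchange symmetry is tested by swapping
weight sets), while sharing the MsM operator keeps the parameter budget
lean.  Zeroing the output projections collapses the block exactly to
U₁ + V₁, which the tests assert bitwise.

### Stages and assembly

* **Encoder stage** (width w): `a = conv(x)`; look-ahead path
  `d = conv(pool(a))`, `u = conv(up(d))`; `m = MCG(a, u)` is the skip
  output; `concat(pool(m), d)` (2w channels) feeds the next stage.
* **Bottleneck stage**: the decoder pattern without a same-level skip
  (no encoder runs at the bottom resolution).  Its `deep` input is the
  encoder bottom tensor; its `skip_below` is the max-pooled deepest skip.
* **Decoder stage** (level i): `t = conv(up(deep))` is computed once and
  used twice — downsampled into the gate path `q = conv(pool(t))` and
  concatenated into the output; `p = conv(concat(deep, skip_below))`;
  `m = MCG(p, q)`; output `conv(concat(up(m), t, skip_same))`.
* **Output stage**: two serial conv blocks cross-gated, then a 1×1
  projection to logits.  The loss applies the sigmoid.

`conv` is always 3×3/stride 1/zero-pad 1 without bias, followed by batch
normalization (affine) and ReLU.  Downsampling is 2×2 max pooling;
upsampling is ×2 bilinear interpolation with half-pixel centres (constant
maps are preserved exactly); channel widths are set by the conv blocks that
follow each upsample.

### Stage widths and cost calibration

The published cost envelope of this architecture — 33.25 M parameters and
≈53.8 GFLOPs at 256×256×3 — is reproduced by construction and acts as the
arbiter wherever the block diagrams admit more than one consistent wiring.
A uniform doubling plan (64/128/256/512) satisfies the parameter budget but
costs ~92 GFLOPs, so the defaults use a plan that is narrow at high
resolution and wide at depth:

| knob | default | note |
|------|---------|------|
| stage widths | 32, 64, 144, 512 | encoder = decoder widths |
| decoder gate widths | 64, 144, 512 | the width of the level below |
| bottleneck gate width | 320 | |
| output-stage width | 52 | fine calibration knob for the parameter budget |
| window base b | 2 | constant across stages |
| hidden_ratio | 1 | dimension-preserving MsM projection |
| dropout | 0.1 | disabled in all oracle tests |

With these defaults `count_parameters` enumerates 33,250,285 scalars
(33.25 M after rounding) and the analytic MAC walk gives 53.53 GFLOPs at
256×256 — within 0.5% of the published 53.8.  FLOPs are counted as conv and
dense multiply-accumulates only (1 MAC = 1 FLOP); normalization,
activations, pooling and interpolation are excluded.  The same convention
puts the classic 64-base U-Net at 54.61 GFLOPs, within ~2% of its published
55.84, which pins the convention.

Valid inputs have H, W divisible by 2^depth·2b (64 for the defaults);
violations raise an error that names the divisor and the minimal valid
padded size.

## Loss and metrics

* **BCE**: standard two-term form, probabilities clipped to
  [1e-7, 1 − 1e-7], mean over pixels.
* **Dice loss**: soft (computed on probabilities), smoothing constant 1.0
  added to numerator and denominator; the tests' closed-form oracles use
  smoothing 0.
* **Combined loss**: 0.5·BCE + Dice.
* **Metrics**: per-image IoU and set-F1 on masks binarized at 0.5;
  if prediction and truth are both empty the score is 1 (avoids 0/0);
  aggregates are arithmetic means of per-image scores.  F1 and IoU are
  linked by F1 = 2·IoU/(1 + IoU), property-tested on random mask pairs.

## Autodiff engine

The package ships a small reverse-mode automatic differentiation engine
over NumPy (`cgmunet.nn`): broadcasted arithmetic, 2-D matmul, shape ops,
reductions, ReLU/GELU/sigmoid, a 3×3 same-convolution via im2col, 2×2 max
pooling and ×2 bilinear upsampling, plus Adam with cosine decay.  Gradient
formulas for every primitive and for the composed layers (Dense, LayerNorm,
BatchNorm, ConvBlock) are checked against central finite differences in
float64.  Max-pool ties are broken toward the first element (argmax
semantics); convolution backward recomputes the im2col buffer instead of
storing it, trading ~30% compute for memory.  Networks run in float32;
optimizer moments accumulate in float64.

## Synthetic data

`SyntheticConfig` defaults describe the study conditions used throughout
the tests: 256×256 RGB frames (tests use smaller frames via explicit
configs), 1–3 lesions per image with radii 8–22% of the frame, contrast
0.35, speckle strength 0.08 and boundary blur 2 px.  A sample is a pure
function of (seed, index): the mask is a union of eccentric ellipses with a
low-harmonic boundary wobble; the image is a smooth Gaussian background
field, contrast-shifted under the mask, Gaussian-blurred, and multiplied by
unit-mean Rayleigh speckle.  Augmentation (rotation, hue/brightness,
crop-and-resize) transforms image and mask jointly; masks stay strictly
binary, and 90° multiples use exact array rotation.

The generator emulates the *qualitative* structure of lesion imagery —
foreground/background contrast, soft boundaries, multiplicative texture —
but not modality physics, anatomy, annotation noise or class imbalance
across patients.  Passing tests therefore demonstrate that the
implementation is correct and trainable, not that any accuracy level
carries over to clinical data.

## Training protocol

Split 7:2:1 (seeded shuffle, rounded shares, remainder to train), batch
size 8, epoch budget 100 — the benchmark protocol this package replicates.
The optimizer is this package's own choice (the protocol leaves it open):
Adam, lr 1e-4, no weight decay, cosine decay to 1% over the run; the choice
is echoed in every run record.  Images are normalized to [0, 1] with no
dataset statistics.  Divergence (non-finite loss) aborts with a diagnostic.
The best-validation-IoU checkpoint is kept; checkpoints embed the
architecture config and round-trip bit-exactly.

Functional tests use reduced problem sizes chosen to keep the suite
CPU-friendly: the capacity test trains a depth-2, widths-(8, 16) network on
eight 64×64 samples for 150 Adam steps at lr 1e-3 (it reaches training
F1 > 0.95 around step 75); the reproducibility test runs two full
generate/train/evaluate cycles on six 32×32 samples and compares metric
CSVs byte-for-byte.

## Known limitations

* CPU-only and NumPy-bound: a full-size 256×256 forward pass takes seconds,
  so the 100-epoch benchmark protocol at full resolution is out of
  practical reach here; the defaults exist to make the architecture itself
  exactly reproducible and analyzable.
* Batch normalization couples predictions to batch composition in training
  mode; evaluation always uses running statistics.
* Run-to-run determinism holds on a fixed machine; across machines, BLAS
  reduction order may change results at float32 precision.
* Binary segmentation only (`num_classes = 1` with sigmoid semantics);
  multi-class heads, boundary metrics and 3-D volumes are out of scope.
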