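# Methods

This note documents the models, conventions, numerical choices and
limitations of `lka3d`.  It is the authoritative description of *what*
the package computes; empirical statements here are limited to what the
test suite and `scripts/acceptance.py` themselves verify.

## Decomposed large-kernel convolution

A dense 3D convolution with C input and output channels and a cubic
kernel of side K has `C·(C·K³+1)` trainable parameters (weights plus one
bias per output channel).  The decomposition replaces it with

1. a **depthwise** convolution of side `2d−1` (one kernel per channel),
2. a **depthwise dilated** convolution of side `K/d` with dilation `d`,
3. a **pointwise** (1×1×1) convolution mixing the C channels,

for `C·((2d−1)³ + (K/d)³ + C + 3)` parameters — the `+3` being the one
bias on each convolution, which the instantiated module carries so its
trainable count equals the formula exactly.  The serial DW∘DWD chain has
a cubic receptive field of side `(2d−1) + d·(K/d − 1)`, verified in the
tests by back-propagating from a single output voxel and measuring the
nonzero gradient footprint.

Valid geometries require `d | K` and an even dilated span `d·(K/d−1)`
(otherwise no symmetric size-preserving padding exists); invalid pairs
are rejected at construction.  Paddings are `d−1` for the depthwise and
`d·(K/d−1)/2` for the dilated convolution, so every convolution in the
chain preserves spatial dimensions at stride 1.

Treating d as continuous, the parameter count is stationary where
`24d² − 24d − 3K³/d⁴ + 6 = 0`.  `optimal_dilation` brackets the root on
`[1, K]` and solves it with Brent's method to 1e−9; a companion helper
reports the best *integer* divisor of K by direct evaluation.  FLOP
counts are modelled as parameter count × voxel count, i.e.
multiply-accumulates of a stride-1 "same" convolution; stride > 1,
grouped (non-depthwise) and 2D variants are out of scope.

## The attention module

For input x with C channels:

```
z   = lReLU(GN(x))                     (slope 0.01, groups min(8, C))
A   = sigmoid(pointwise(DWD(DW(z))))
out = A ⊗ z + z
```

A lies strictly in (0,1), so out/z ∈ (1,2) wherever z ≠ 0: the module
re-weights features spatially and per channel but cannot null them.
Design choices that were genuinely open:

- **Convolution order.** The chain is applied DW → DWD → pointwise; the
  reverse order is available as `order="dwd_first"`.  Both orders have
  identical parameter counts and receptive fields, and the choice is a
  recorded config switch for exactness studies.
- **Residual.** The default adds the normalised-activated input z (the
  form the module equations specify); `residual="raw"` adds the raw
  input instead and is off by default.
- **Normalisation.** Group count for GN is unspecified upstream; we use
  `min(8, C)` groups with per-channel affine parameters.  The affine
  terms (2C) are *not* part of the decomposition formula and are
  reported separately in all parameter accounting; `gn_affine=False`
  removes them.
- **Initialisation.** He fan-in normal weights, zero biases, unit/zero
  GN affine, all drawn from a seeded generator: construction is
  bit-reproducible.

An undecomposed variant (`OriginalLKAttention3d`, one dense K³
convolution) exists for parameter-comparison purposes; its forward pass
is only defined for odd K (even kernels cannot preserve size
symmetrically) but it can always be constructed and counted.

## Network architecture

Six scales by default, encoder channels 32, 64, 128, 256, 512, 512
(doubling capped at 512); each scale is two 3³ convolutions with GN and
leaky ReLU; scales are bridged by stride-2 3³ convolutions (with GN +
lReLU) going down and 4³ stride-2 transposed convolutions (kernel 4,
stride 2, padding 1 — exact doubling) going up.  Skip connections
concatenate; the first decoder convolution maps 2C → C.  The deepest
feature map is 1/32 of the input, so input dims must be divisible by
2^(scales−1).

**Attention placement.** A module can be placed directly after any
transposed convolution, *before* concatenation with the skip — the only
placement consistent with decoder channel counts 512/256/128/64/32 from
coarsest to finest.  The canonical variants: *Base* (none), *Mid* (one
equal-21 module at the middle decoder scale, C=128), *Full* (modules at
all five decoder scales with kernels 6, 6, 10, 15, 21 coarse→fine).

**Deep supervision.** 1×1×1 segmentation heads sit at every scale except
the two lowest (four heads for six scales).  Auxiliary losses are
computed against nearest-neighbour-downsampled labels with geometric
weights 1, 1/2, 1/4, … normalised to sum to one (the weighting is this
package's choice).

**Parameter accounting.** `parameter_breakdown` reports every component;
the placement-additivity identity — variant minus Base equals the sum of
`C·((2d−1)³+(K/d)³+C+3)` over placements (conv-only; module GN affine
2C reported separately) — is the primary architecture check and is
asserted exactly in the tests: +76,672 (Mid), +444,064 (Full), +291,328
(deepest decomposed), 56,623,616 (deepest original).  The Base network
as specified here totals 100,988,988 parameters; the published total for
the same design is 101,017.22 k, which our construction matches to
0.028 % — the residual depends on undocumented details of the original
implementation and cannot be reconciled further from the architecture
description alone.  The relative cost of Mid attention,
76,672 / base total, is 0.0759 %.

## Losses

- **Weighted soft Dice** (multi-organ, softmax heads): per foreground
  class, `softDice_c = (2Σpt + ε)/(Σp + Σt + ε)` with ε = 1e−5; loss is
  `1 − Σ w_c·softDice_c / Σ w_c`.  Normalising by the weight sum, and
  excluding the background channel from the loss classes, are this
  package's choices (both were unspecified upstream).  Class weights are
  `1 − foreground/background` voxel ratios computed over the whole
  training set (dataset-level, stable across epochs), clamped to [0,1];
  an absent class gets weight 1 with a warning.
- **BCE + Dice** (region channels, sigmoid heads): mean binary
  cross-entropy plus unweighted soft Dice over the channels, 1:1.
  Probabilities are clipped to [1e−7, 1−1e−7] inside the BCE.

## Metrics

- **Dice** `2|X∩Y|/(|X|+|Y|)`; both masks empty → 1 (convention).
- **HD95**: the printed percentile-of-a-max formulation is degenerate
  (a percentile of two scalars), so the implementation follows the
  textual definition — the 95th percentile of the *pooled* directed
  boundary-to-boundary distances of both directions, computed with
  Euclidean distance transforms under the voxel spacing (mm).  The
  directed-max alternative is `method="directed_max"`.  Boundaries are
  6-connectivity erosion differences; volume-edge voxels count as
  boundary.  Identical masks → 0; both empty → 0; exactly one empty →
  +inf unless a penalty convention applies.
- **False-positive convention**: for an enhancing-tumor channel with
  empty reference and non-empty prediction, Dice 0 and HD95 373.13 (the
  challenge convention this field uses).
- **Regions**: ET = label 4, TC = ET ∪ label 1, WT = TC ∪ label 2;
  nesting ET ⊆ TC ⊆ WT holds by construction.
- **Paired t-test**: two-sided on per-case differences, implemented from
  the closed-form t statistic and the t distribution; degenerate inputs
  (n < 2 or zero-variance differences) raise instead of returning a
  number.

## Preprocessing and augmentation

Resampling Gaussian-smooths each axis that is being coarsened
(σ = downsampling factor / 3 — the smoothing constant is this package's
choice) before trilinear interpolation; labels are nearest-neighbour
resampled without smoothing; output dims are `round(dims·spacing/target)`.
Center crop/pad records its inverse so predictions can be written back
onto the original grid.  Intensity normalisation: z-score over nonzero
voxels for MR (background stays 0), clip to the 0.5/99.5 intensity
percentiles then z-score for CT.

The augmentation policy (probability, range): brightness 0.30,
U(0.7, 1.3) multiplicative; contrast 0.15, U(0.6, 1.4) about the channel
mean; Gaussian noise 0.15, σ ~ U(0, 1) (the published table conflates
variance and σ; we draw σ); Gaussian blur 0.20, kernel σ ~ U(0.5, 1.5);
gamma 0.15, γ ~ U(0.7, 1.5) applied after min–max mapping to [0, 1];
scaling 0.30, U(0.65, 1.6) about the center; rotation 0.30, Euler angles
U(−30°, 30°); elastic 0.30, amplitude α ~ U(5, 10) voxels with field
smoothing σ = 3α; flipping 0.50, each axis independently at 0.5 once the
transform fires.  Spatial transforms warp image (trilinear) and label
(nearest) identically; intensity transforms never touch the label; every
draw comes from one seeded generator, so the whole pipeline is bitwise
reproducible.

## Synthetic phantoms

`generate_phantom` builds the test-bed volumes: axis-aligned ellipsoidal
"organs" (default two blobs per class, semi-axes 5–10 voxels on a 64³
grid) placed by rejection sampling so classes never overlap (bounded
retries, loud failure), over a Gaussian background (σ = 0.05), with
class intensities at evenly spaced means 0.4 … 1.0 (σ = 0.05) — about a
6-σ separation between neighbouring classes, i.e. clearly but not
trivially separable.  Phantoms emulate the *geometry* of multi-organ
volumes (compact structures of distinct intensity, class imbalance
against a dominant background) but not partial-volume effects, organ
contact surfaces, anatomy-dependent texture, or scanner artefacts — so
passing phantom tests demonstrates the pipeline's mechanics and
trainability, not clinical accuracy.

## Training

Adam (β = 0.9/0.999, no weight decay), initial learning rate 3e−4,
200 epochs, batch size 1 — the package defaults.  The learning-rate
schedule is polynomial decay with power 0.9 (a constant schedule is a
switch); schedule, β and the absence of weight decay are explicit,
logged choices, not upstream claims.  Training logs (epoch, step, loss,
loss components, lr, seed) are written as CSV; checkpoints (versioned
NPZ with config + weights + seed) save best-by-loss and last.  NaN loss
aborts with the offending case and loss components.  Data order,
augmentation and initialisation all derive from the config seed, so two
runs with the same seed produce identical loss curves.

## Compute engine and problem sizes

The networks run on a small reverse-mode autodiff core over float32
NumPy arrays (`lka3d.nn`): broadcast-aware elementwise ops, group-norm
and activation primitives, and im2col 3D convolutions (dense and
depthwise, arbitrary stride/dilation) whose gradients are exercised by
adjointness identities and finite differences in the test suite.  The
transposed convolution is evaluated phase-by-phase on the coarse grid,
never materialising a zero-stuffed volume.  im2col buffers are filled
with one strided copy per kernel tap, processed in output-depth slabs
(≤ 64 M floats), and drawn from a reused scratch pool to avoid
large-allocation churn.

This engine is meant for desk-scale work, so the package's own tests use
reduced problem sizes: full-resolution (160×192×128) *forward passes*
are not run — parameter accounting is done by construction, and shape
contracts are exercised on smaller divisible-by-32 grids — while the
end-to-end memorisation check trains a tiny mid-attention variant
(base width 8, four scales) on a single 64³ phantom with early stopping
once mean foreground Dice reaches 0.8.  The memorisation run uses the
per-class sigmoid heads with the BCE + Dice objective at a constant
learning rate of 2e−3: independent binary channels give well-conditioned
gradients for single-volume memorisation.  The background-excluded
weighted soft Dice objective, by contrast, admits a recall-perfect /
precision-poor plateau at this problem size (the softmax mass of
background voxels can sit on a foreground class with only a weak
gradient pushing it out), so it needs far more than a few hundred steps
to resolve — a known property of Dice-only objectives, not a defect of
either loss at production scale, where many volumes and epochs break the
plateau.

## Known limitations

- No sliding-window inference: volumes are segmented whole, so grid size
  is bounded by memory.
- No DICOM ingestion, registration or skull-stripping; inputs are
  assumed co-registered NIfTI.
- The undecomposed large-kernel module cannot run forward with even K.
- Single-process, CPU-only; no mixed precision, no multi-GPU.
- The published Base-network total is matched to 0.028 %, not exactly
  (see Parameter accounting above).
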