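# Methods

## Problem and pipeline

Plantar thermograms image the temperature field of the sole of the foot.
In diabetic patients, focal hyperthermic regions correlate with elevated
risk of foot ulceration, so two tasks matter clinically: delineating the
hot-spot lesions (segmentation) and separating diabetic (DM) from control
(CG) subjects (classification).  `thermoseg` implements an integrated
pipeline for both:

1. **U-MST segmenter** — a U-shaped encoder–decoder whose blocks are
   windowed-attention transformer blocks.
2. **Capsule feature extractor** — primary capsules over the decoder
   bottleneck, routed by agreement into a small set of output capsules,
   flattened into a feature vector `Z`.
3. **ELM classifier** — a single-hidden-layer network with random frozen
   hidden weights whose output weights are solved in closed form by ridge
   regression on `Z`.

Training is two-phase.  Phase one jointly optimizes segmenter and capsule
extractor with ADAM on

    L_total = α · L_seg + β · L_cls ,      α = 0.6, β = 0.4

where `L_seg` is a soft Dice loss on the foreground probability map and
`L_cls` a categorical cross-entropy on a capsule-side softmax head used
only during backpropagation.  Phase two freezes the network and fits the
ELM on the frozen capsule features of the training subjects.  A closed-form
classifier cannot be trained jointly by gradient descent, so this two-phase
split is the only internally consistent protocol; the softmax training head
exists to give the capsule features a discriminative gradient signal.

## The segmenter

**Blocks.** Each block is pre-norm residual:

    u   = x + Attn(Norm(x))
    out = u + MLP(Norm(u))

with `Norm` either LayerNorm (standard block) or per-channel BatchNorm over
(batch, height, width) (the "modified" block, the default), and `MLP` two
affine maps with a GELU and hidden width `mlp_ratio · dim`.  The attention
is one of:

- **W-MHSA** — multi-head scaled-dot-product attention restricted to
  non-overlapping `window × window` tiles, with a learned relative position
  bias per head;
- **SW-MHSA** — the same after a cyclic roll by `window/2`, with an additive
  mask (−10⁹ on the logits) that removes attention between tokens that were
  not neighbours before the roll.  The exponential underflows to exactly
  zero weight, which the tests assert;
- **SW-HCMA** — hybrid channel–spatial gating inside shifted windows: a
  channel gate `σ(MLP(avgpool) + MLP(maxpool))` per window and a spatial
  gate `σ(conv3×3([avgmap, maxmap]))`, both applied multiplicatively.

Within a stage, blocks alternate unshifted attention (even positions) and
shifted attention (odd positions); odd blocks use SW-HCMA when the hybrid
attention is enabled (`use_hcma`, the default) and SW-MHSA otherwise.  When
the token grid is no larger than one window the shift is dropped — a shift
of a single-window grid only permutes tokens.

**Encoder.** A patch-embedding layer (4×4 patches, linear projection to
`embed_dim`) followed by three stages; stages 2–3 begin with patch merging
(2×2 token concatenation, linear 4C→2C), so the grid halves and the width
doubles per stage: for 64×64 input and `embed_dim` 32 the stage outputs are
16×16×32, 8×8×64, 4×4×128.

**Feature fusion.** Each stage map is downsampled with a 2×2 stride-2
convolution, concatenated channelwise with the next stage's map, and
projected back to that stage's width.  The deepest fused map feeds the
decoder.  A `use_fusion` flag disables the module for ablations.

**Decoder.** A bottleneck block, then two stages of (2× nearest upsample,
skip-concatenate with the matching fused map, linear projection, transformer
block), mirroring the encoder.  The head applies a final LayerNorm, then a
*patch-expansion* projection: each token is mapped linearly to a
`patch_size²` block of sub-pixel features, restoring full resolution, and a
3×3 refinement convolution over the expanded features concatenated with the
raw input image produces the class logits.  Two of these choices were made
after observing optimization behaviour and deserve a note:

- the final LayerNorm bounds the logit scale; without it, Dice-loss training
  occasionally saturated the softmax into an all-background state it could
  not leave (the Dice gradient vanishes under a saturated softmax);
- a bilinear-upsample head smooths the probability map over a
  `patch_size`-wide band around every boundary, which caps achievable soft
  Dice for lesions only a few pixels across; learned patch expansion plus an
  image-conditioned refinement conv makes boundary decisions local and
  sharp.

**Dice loss.** `1 − (2Σpt + ε)/(Σp + Σt + ε)` over the batch, on the
foreground softmax probability `p`, with `ε = 1.0` so all-background
targets stay finite.

## Capsules

`squash(v) = (‖v‖²/(1+‖v‖²)) · v/‖v‖` bounds capsule norms into [0, 1)
while preserving direction (a 10⁻¹² floor under the square root makes
`squash(0) = 0` exact).  Primary capsules are a 1×1 convolution over the
decoder bottleneck reshaped into pose vectors and squashed; when
`use_mask_channel` is on (default) the predicted foreground probability,
average-pooled to the bottleneck grid, is appended as an extra input
channel — the predicted lesion field is the single most discriminative
cue for the classifier.  Routing-by-agreement runs `routing_iters = 3`
iterations: logits `b_ij` start at zero, couplings are a softmax over the
output index, weighted prediction sums are squashed, and `b_ij` is
incremented by the prediction–output dot product (the agreement update is
kept outside the gradient tape, as is conventional).  Transformation
matrices are shared across primary capsules ("global parameter sharing"),
keeping the routing layer small.  With one iteration the procedure reduces
to uniform coupling — the closed form the tests check.

## ELM

Hidden weights and biases are drawn once from Uniform(−1, 1) and never
updated; activations are sigmoid.  Output weights solve the ridge system

    β = (I/C + HᵀH)⁻¹ HᵀO        (primal, N > L)
    β = Hᵀ (I/C + HHᵀ)⁻¹ O       (dual,   N ≤ L)

which coincide for any C > 0 and approach the Moore–Penrose solution
`H⁺O` as C → ∞.  Class probabilities are a softmax over `h(x)β`.  The
cross-entropy loss helper defaults to averaging over samples; a
feature-length normalizer is available behind the `over_features` argument
for compatibility with the convention that divides by the capsule feature
length instead.

## Training protocol

Defaults: initial learning rate 0.001, ADAM (β₁ = 0.9, β₂ = 0.98 — the
smaller second-moment constant is the usual choice for transformer
stability), batch size 30, up to 289 epochs, early stopping on a held-out
validation split (10 % of training subjects, at least one; patience 20,
min-delta 10⁻⁴) with best-weights restore (parameters *and* batch-norm
running statistics).  A `momentum` value of 0.02 is carried in the config
for provenance; ADAM does not use it, and an SGD fallback
(`optimizer: sgd`) consumes it as classical momentum.  Global gradient-norm
clipping at 1.0 and an optional cosine learning-rate schedule are available.
Dropout, when swept, applies to the MLP hidden layers.

Cross-validation is stratified at subject level: subjects are shuffled
within class and dealt round-robin into five folds, so every subject is
tested exactly once and each fold preserves the DM/CG proportions to within
one subject.  Augmented copies are created from training-fold records only,
after the split, so no augmented view of a test subject ever reaches
training — the alternative (augmenting before splitting) leaks.

## Synthetic data

The generator emulates a two-group plantar-thermogram cohort whose default
composition matches the study this package models (122 DM / 45 CG):

- a foot-shaped binary support (sole and heel ellipses plus five toe
  discs);
- a smooth low-frequency temperature field on the support (baseline 0.35
  relative units, ±0.06 gradients, a cooler arch), 0.08 off the support;
- additive Gaussian sensor noise, σ = 0.02;
- for DM subjects, 1–3 radially Gaussian hot spots of contrast 0.35
  (relative units) and radius parameter 4–8 px at 64×64, placed wholly on
  the sole and mutually disjoint.  The ground-truth mask is the half-maximum
  footprint of each lesion, so lesions occupy a realistic few percent of the
  sole.

Intensities are relative temperature in [0, 1], not calibrated degrees;
images are stored as 16-bit PNG, masks as 8-bit PNG, with a CSV manifest.
File names follow `{group}{code}{gender}_{side}.png` (e.g. `DM003F_left`).
Class indices are CG = 0, DM = 1.

What the generator does **not** emulate: camera calibration and radiometric
units, pose and perspective variation, limb occlusion or amputation,
bilateral asymmetry cues, skin-condition artefacts, and the diffuse,
irregular lesion geometry of real ulcers.  Passing tests on this data shows
the pipeline's mechanics (shapes, losses, routing, closed-form fits,
optimization, CV bookkeeping) work and that the architecture can learn
hot-spot segmentation; it does not certify clinical performance on real
thermograms.

## Preprocessing

- **Pixel screening**: a Hampel-style filter — pixels deviating more than
  `k = 3` neighbourhood MADs from their 3×3 neighbourhood median are
  replaced by that median.
- **Histogram enhancement**: CLAHE (8×8 tiles, clip limit 0.02); constant
  images pass through unchanged.  Disabled by default in the CV harness:
  on the synthetic images local equalization amplifies background noise
  relative to lesion contrast.
- **Augmentation**: affine translate/scale/rotate, sampled uniformly
  (defaults ±8 % translation, scale 0.9–1.1, ±15°), bilinear for images,
  nearest-neighbour for masks (masks stay binary); transforms that would
  push more than half the mask foreground out of frame are resampled.

## Desk-scale problem sizes

The package runs on a plain CPU via its own NumPy autodiff engine, so the
shipped experiment sizes are deliberately small: the cross-validation
demonstration uses a 30 DM / 12 CG cohort at 64×64 with lesion contrast
0.5, a 3-stage model with `embed_dim` 16 and depths (2, 2, 2), batch 8,
up to 80 epochs per fold; the learnability check overfits 8 images with
`embed_dim` 32 and depths (1, 1, 1) for 200 epochs.  These sizes are a
design choice for a reproducible desk-scale artifact, not a limit of the
method; all dimensions scale through the config.

## Numerical choices and degenerate inputs

- float64 throughout; attention mask constant −10⁹ (underflows to exact
  zero weight after softmax); softmax is max-shifted.
- `squash(0) = 0` via the ε-guarded norm; routing couplings from zero
  logits are exactly uniform.
- Empty-mask conventions: Dice/IoU/precision/recall are all 1 when both
  masks are empty, and precision (recall) is 0 when the prediction (truth)
  alone is empty.
- Ridge systems are solved with `numpy.linalg.solve` on the smaller of the
  primal/dual Gram matrices; C > 0 keeps them positive definite.
- Ties in max-reductions split gradient mass evenly among the argmaxima.

## Known limitations

- No GPU path; wall-clock is the price of a dependency-free engine.
- BatchNorm uses batch statistics in training; very small batches make the
  estimates noisy (batch 8 at 16×16 tokens is already ample in practice).
- Binary segmentation only (lesion vs background); `n_seg_classes` is
  plumbed through but multi-class region taxonomies are out of scope.
- The dropout-stability sweep retrains scaled-down models; it is a
  qualitative stability probe, not a calibrated sensitivity analysis.
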