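# Methods

## Model

The segmenter is a four-stage U-shape encoder–decoder. Encoder stages are
structured residual blocks — two `conv3x3 → DropBlock → BatchNorm → ReLU`
units plus an additive skip (identity, or a biased 1×1 projection when the
channel count changes) and a final ReLU — separated by 2×2 max pooling, so the
bottleneck runs at 1/16 resolution and inputs must have sides divisible
by 16. The bottleneck is the scale-aware dense residual (SDR) module: dilated
3×3 branches at rates (1, 3, 5), each `conv → BN → ReLU`; adjacent branch
pairs are merged by elementwise addition, passed through a transfer layer
(`conv3x3 → DropBlock → BN → ReLU`), converted to a channel-softmax weight
mask, and fused as `mask ⊗ (D_a ⊕ D_b)`; a bias-free 1×1 convolution of the
block input provides a dense residual skip, and `1×1 conv → BN → ReLU` fuses
the two pair outputs with the skip. Decoder stages upsample 2× (bilinear by
default; a learned 2×2/stride-2 transposed convolution is selectable), gate
the matching encoder skip with a spatial attention gate using the upsampled
decoder features as the gating signal, concatenate gated skip and decoder
features, and apply a structured residual block.

Each decoder stage carries an output head: upsample to input resolution by
its stage factor (1, 2, 4, 8), then `1×1 conv → BatchNorm → ReLU`, then a
sigmoid to produce a probability map. The shallowest head (`out1`, factor 1)
is the prediction; binarization is `p > threshold` (strict), threshold 0.5 by
default. Under this head a background pixel saturates at exactly p = 0.5 once
its pre-sigmoid activation is clipped by the ReLU, which is classified as
background by the strict inequality; an alternative `1×1 conv → sigmoid` head
without the BN+ReLU stack is selectable (`head: sigmoid`) for users who want
calibrated background probabilities.

In the attention gate, both inputs are first projected by independent 1×1
convolutions to a common intermediate width (default: half the encoder skip's
channels, minimum 1), summed, passed through ReLU then BatchNorm, reduced to
one channel by a biased 1×1 convolution, and squashed by a sigmoid; the
single-channel mask multiplies every channel of the encoder skip.

## Loss

Each head is scored with mean class-weighted binary cross-entropy,
`−[w₁ y ln p + w₂ (1−y) ln(1−p)]` with probabilities clamped to
[1e-7, 1−1e-7]; the mean (rather than sum) reduction keeps the loss-weight
scales independent of image size. Head losses combine as
`α(loss₂+loss₃+loss₄) + (β−α)loss₁` with α = 0.125 and β = 1.0 (DRIVE
profile) / 0.9 (STARE profile); the constraint β ≥ α ≥ 0 is enforced because
a β below α would weight the final head negatively. Default class weights
w₁ = 0.8 (vessel) and w₂ = 0.2 counter the roughly 1:9 vessel:background
imbalance. The same (w₁, w₂) apply to all heads.

## Training

Adam with constant learning rate 0.001 (no schedule), batch size 2, and
120–150 epochs (default 130) for a full run. DropBlock uses drop probability
0.18 and block size 3; the Bernoulli seed rate is calibrated as
γ = p/b² · HW/((H−b+1)(W−b+1)) so the realized zeroed fraction matches p, and
survivors are rescaled by total/kept so activations keep their expectation.
Convolutions that feed directly into BatchNorm are bias-free (the
normalization cancels any constant channel offset, making such biases
unidentifiable with identically-zero gradients). BatchNorm uses momentum 0.1,
eps 1e-5, biased batch variance, and running statistics in inference. Weights
are He-normal initialized from a generator seeded by the run seed; DropBlock
mask streams and batch shuffling derive from the same seed, so a run is fully
reproducible on a fixed device, and the resolved configuration is written
next to the checkpoints. Both the final-epoch checkpoint and (when a
validation fraction is configured; default 0) the best-validation-dice
checkpoint are kept. A non-finite loss aborts with a diagnostic.

The network is implemented on a small NumPy reverse-mode autodiff core
written for this package (tape-based; convolutions evaluated tap-by-tap with
BLAS contractions). Every differentiable operation is checked against central
finite differences in the test suite, and composite modules are additionally
checked against manual layer-by-layer recompositions.

## Evaluation

Pixel confusion counts (optionally restricted to a field-of-view mask; the
default uses the full image) feed dice, accuracy, binary mIoU (the mean of
foreground and background IoU) and recall. Reports carry one row per image
plus an aggregate; the default aggregation is macro (mean of per-image
metrics) with pooled-count micro aggregation selectable. Degenerate
denominators return 1.0 when the corresponding error counts are zero and 0.0
otherwise, with a warning — e.g. recall on an all-background ground truth is
1.0 only for an all-background prediction.

## Synthetic data

The generator emulates the statistics that drive the method's design choices:
sparse curvilinear foreground (target vessel fraction 6–14%, matching the
imbalance the loss weights assume), branch widths tapering by 0.7 per
generation down to one-pixel capillaries (the thin-structure regime),
tortuous strokes (heading jitter 0.25 rad/step), an illumination-graded
red-dominant background, and mild sensor noise (Gaussian σ = 0.02,
salt-and-pepper rate 0.005). Stroke width is defined at a 64-pixel reference
scale so the vessel fraction is resolution-independent. Masks are redrawn
(bounded retries) until the fraction lands in the target interval. Defaults
(64 px, 3 trees, depth 3, root width 2.4) were chosen once as a realistic
miniature of fundus geometry.

What it does not emulate: optic disc and macula, lesions, inter-image color
and contrast variation, annotation ambiguity, and the resolution of real
fundus cameras. Passing the suite therefore demonstrates that the
architecture, losses, training loop and tooling are wired correctly and can
learn curvilinear structure under class imbalance — not that the reported
desk-scale metrics transfer to DRIVE/STARE-scale benchmarks, which require
full-size training runs with the shipped `drive`/`stare` profiles.

## Numerical and design choices

- Probability clamp 1e-7 before logarithms; clip gradients pass only through
  unclamped entries.
- Max-pool ties route the gradient to the first maximum.
- Bilinear upsampling uses half-pixel centers (align_corners=False
  convention) and, being linear, backpropagates through the transposed
  interpolation matrices.
- Threshold ties (p == threshold) are background: foreground requires strict
  inequality.
- The two SDR transfer layers, and the two 1×1 projections inside each
  attention gate, have independent weights.
- The SDR bottleneck width defaults to the last encoder width (256 at the
  default stage widths 32/64/128/256; widths are configurable and the
  defaults keep CPU runs tractable).
- STARE's 15/5 train/test convention is applied over sorted ids (first 15
  train); the split is configurable and recorded in the persisted config.
- Training uses full images (no patch extraction); images with sides not
  divisible by 16 are handled at prediction time by an explicit
  reflect-pad-and-crop option rather than implicit padding.
- Augmentation is offline expansion (each op yields a new sample): flips,
  right-angle rotations (applied identically to image, mask and FOV), and
  Gaussian/salt-pepper noise (image only), all seeded. Noise defaults
  σ = 0.02 and rate = 0.02 on the [0, 1] scale, applied after normalization
  and clipped back.

## Desk-scale problem sizes

The test suite and the acceptance script exercise the full default network on
8 synthetic 64×64 images with 200 optimizer steps (batch 2), which reaches
training dice > 0.9 and shows the auxiliary-head speedup; smaller stage
widths (4/8/16/32) are used where only wiring is under test. These sizes are
the package's own choice of a minimal configuration that still exhibits the
phenomena of interest.

## Known limitations

- CPU-only: fine for desk-scale runs and full-image DRIVE training at small
  batch, but slow for hyperparameter sweeps.
- The BN+ReLU output head floors background probabilities at 0.5 (see above);
  use the `sigmoid` head if downstream consumers need calibrated
  probabilities rather than a thresholded mask.
- No CLAHE/green-channel preprocessing, patch-based inference, or test-time
  augmentation; no AUROC or topology-aware (e.g. centerline) metrics.
- DropBlock requires the feature map to be at least block_size wide; with
  block size 3 the smallest trainable input is 48×48 (bottleneck 3×3).
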