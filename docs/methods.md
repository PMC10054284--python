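# Methods

This note records the modelling choices behind `surgmtl`, the defaults and
why they were chosen, and what the synthetic benchmark does and does not
demonstrate.

## Model

The network is a shared-trunk multi-task architecture. One encoder serves
both tasks; task interaction happens only through the shared weights, which
are trained to minimize the plain sum of the two task losses (unit weights,
no uncertainty weighting or schedule). The assumption behind sharing is that
the cues are correlated: active bleeding usually coincides with an
instrument interacting with tissue, and recedes when the aspirator works, so
features learned for tool segmentation are informative for the event class.

Architecture specifics:

- Encoder level k has `base_channels · 2^k` channels (defaults: 64, 128,
  256, 512 with a 1024-channel bottleneck at depth 4). Each level is two
  padded 3×3 convolutions with ReLU followed by 2×2 max-pooling.
- The two bottleneck convolutions are also followed by ReLU. Without a
  nonlinearity two stacked convolutions collapse into one linear map, so the
  activation is applied even though descriptions of this family of
  architectures sometimes leave it implicit.
- Decoder blocks upsample by nearest neighbour, halve channels with a 2×2
  convolution (asymmetric (0,1,0,1) padding keeps the size under the even
  kernel), concatenate the symmetric encoder map, and apply two padded 3×3
  convolutions with ReLU. The up-convolution itself carries no ReLU.
- The segmentation head is a single 1×1 convolution producing one logit map:
  the tool/background decision is binary, so one sigmoid channel suffices.
- The classification head flattens the bottleneck (this is what ties the
  architecture to a fixed input size, and why input dimensions must be
  divisible by 2^depth) into two 1024-wide linear+ReLU+dropout stages and a
  final linear layer over 2 classes. Dropout probability defaults to 0.5,
  applied after each of the two hidden stages exactly.
- Input images are RGB scaled to [0, 1]; no normalization statistics are
  learned or required.
- Initialization: He-style normal for convolutions, uniform ±1/√fan_in for
  linear layers, drawn from a generator seeded by `ModelConfig.seed`, making
  weight initialization reproducible.

The implementation (`surgmtl.nn`) is plain NumPy with hand-written backward
passes. Convolutions run as kh·kw shifted GEMMs accumulated in NCHW layout —
for 3×3 kernels this is markedly faster in NumPy than an explicit im2col
gather. Max-pool ties route the gradient to the first maximum, which keeps
the backward pass deterministic. Correctness of every layer's gradient is
established by central finite differences in float64 in the test suite, and
the forward convolution is cross-checked against `scipy.ndimage.correlate`.

## Loss and metrics

- `total = seg_loss + cls_loss` exactly; both terms are means (over pixels
  and batch for the segmentation term, over samples for the classification
  term). Both are computed in numerically stable logit form equivalent to
  activation-then-loss.
- Dice is computed on binarized masks (threshold 0.5 on the sigmoid) with
  exact integer pixel counts; the dataset-level value is the unweighted mean
  of per-image Dice. Soft (probabilistic) Dice is deliberately not used: the
  definition is stated on pixels. The empty-vs-empty case (0/0) is defined
  as 1.0 — two empty masks agree perfectly.
- Per-class accuracy for class c is accuracy restricted to samples whose
  *target* is c; the overall accuracy is then the sample-count-weighted mean
  of the per-class values (an identity the tests assert).
- At inference the event probability is the softmax class-1 component; a
  sample is called class 1 when that probability is ≥ 0.5.

## Synthetic scenes

Clinical video of robot-assisted radical prostatectomy cannot be
redistributed, so the package ships a parametric scene grammar that
reproduces the *structure* of such data at the reference dataset scale
(200/32/86 train/val/test images, 318 total):

- a tissue-coloured background with a smooth multiplicative illumination
  field and Gaussian texture noise;
- 0–3 dark-red elliptical blood pools;
- 1–2 elongated gray rotated-rectangle instruments drawn on top, so
  instruments occlude blood as they do in real footage.

Ground truth is self-consistent by construction: the tool mask is exactly
the rendered instrument footprint, `blood_fraction` is the visible pool area
over the image area, and the event label is 1 iff `blood_fraction ≥ τ`. The
default τ = 0.08 was chosen so both classes occur at workable rates under
the default geometry; splits of size ≥ 8 are rejection-resampled so each
class covers at least a quarter of the split (real class ratios are
unknown). The τ area rule is an explicit, reproducible proxy for what is, in
clinical labeling, an expert judgment ("is blood accumulating enough to need
intervention?"); it is not a claim about how clinicians decide.

Augmentation draws a rotation uniformly from (−35°, 35°) and one of
{none, horizontal, vertical, both} flips, applied identically to image and
mask (bilinear for the image, nearest for the mask, mask re-binarized).
Rotation fills exposed corners with the tissue base colour rather than
black so augmented images keep scene-like colour statistics. A zero-angle
transform skips the warp entirely, which makes pure flips exact involutions.

What passing on this benchmark does **not** show: robustness to specular
highlights, smoke, motion blur, lens distortion, changing illumination
colour, blood residue vs active bleeding ambiguity, or temporal dynamics.
The synthetic task is deliberately much easier than the clinical one; the
benchmark demonstrates that the architecture, losses, training loop and
inference plumbing are correct and can learn, not that the model would reach
clinical-grade accuracy.

## Training protocol

Reference defaults mirror the protocol the architecture was designed for:
30 epochs, batch 32, Adam (lr 1e-4, β₁ = 0.9, β₂ = 0.999), augmentation on
the training split only, final-epoch checkpoint (selection by best
validation Dice is available by flag). The last incomplete mini-batch is
kept. No learning-rate schedule, weight decay, or early stopping. One seeded
generator drives shuffling, augmentation, and dropout, so identical
(seed, data) reruns reproduce the history bit for bit on the same BLAS.

The acceptance suite's learning checks run at reduced problem sizes chosen
as a sensible desk-scale configuration: a base-16, depth-3, hidden-256
variant of the architecture, Adam at 1e-3 with batches of 8–16, on 64×96
(memorization check: 8 samples, 300 steps) and 96×128 (generalization
check: 200 training scenes, 10 epochs, 32 validation scenes). The larger
step size reflects the short optimization horizon of these runs — at 1e-4 a
few hundred Adam steps barely move the weights regardless of model quality.
With these settings the held-out split reaches Dice ≈ 0.95 and accuracy 1.0
on the easy synthetic task.

## Video runtime

- The prediction stride k means one network invocation every k frames
  (k = 1: every frame); skipped frames reuse the last mask and percentage —
  the freshness/throughput trade-off of a live overlay. Strides above 30 are
  rejected: at 30 fps input that would refresh slower than once per second,
  too slow for a bleeding alert.
- The first prediction is at frame 0, so every frame has a defined
  annotation.
- Frames are resized (aspect-distorting bilinear) to the network input size
  for inference; the predicted mask is upscaled back with nearest neighbour
  for rendering at the original resolution.
- The banner shows the class-1 softmax probability as a percentage, rounded
  for display (the raw float is kept on the `AnnotatedFrame`), and only when
  strictly greater than the display threshold (default 50%).
- Throughput (frames per second) is measured and logged but never asserted:
  it is hardware-dependent.

## Numerical and degenerate-input choices

- Mask binarization threshold 0.5; sigmoid/softmax computed in
  overflow-safe form.
- `MaxPool` requires even spatial dims (guaranteed by the divisibility
  invariant); pooling ties are resolved toward the first maximum.
- Zero-area tool draws are resampled inside the generator (never emitted);
  class-balancing resampling aborts with a clear error if a configuration
  makes one class pathologically rare.
- Checkpoints store config + weights + seed in one `.npz`; loading refuses a
  checkpoint whose stored config disagrees with the requested one.
- Dice of two empty masks is 1.0 (see above); `classification_accuracy`
  rejects empty inputs.

## Known limitations

- CPU-only NumPy training: practical for the desk-scale configurations
  above, not for the full 64-base-channel network at 160×240 — that
  configuration is instantiated and run forward in tests, but training it is
  out of desk scope.
- No temporal modelling: each frame is classified independently; the stride
  cache is a latency optimization, not a temporal smoother.
- Binary tool class only; no bleeding-source localization; no multi-device
  support. These are deliberate non-goals.
- Bit-exact reproducibility holds for a fixed BLAS/platform; across
  different BLAS builds, floating-point reduction order may differ.
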