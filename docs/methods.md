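# Methods

`frycount` implements density-map regression for counting shrimp fry
(*Penaeus vannamei* post-larvae) in top-down photographs of shallow rearing
tanks, together with a synthetic scene generator that stands in for the
private imagery such systems are trained on.

## Ground-truth density maps

Each image is annotated with one sub-pixel point `x_i = (x, y)` per animal
(0-based, x = column, y = row).  The annotation field is the sum of unit
impulses `H(x) = Σ_i δ(x − x_i)`; the regression target is its convolution
with an isotropic Gaussian kernel

    F(x) = Σ_i δ(x − x_i) * G_σ(x),   G_σ(x) = exp(−‖x‖² / 2σ²) / 2πσ²

with a fixed σ = 3 px.  The defining property is conservation: the map's
integral equals the count, so a predicted map can be read out by summation
("count-by-integration").

Numerical choices:

- Kernels are centered at the continuous coordinate and evaluated at pixel
  centers; the impulse matrix (provided separately for completeness) rounds
  to the nearest pixel with ties toward +∞.
- For speed each kernel is truncated to a per-axis window of half-width
  `truncate·σ` (default 4σ).  By default every point's on-grid mass is then
  renormalized to exactly 1, which makes `integral = N` hold to float
  precision even for points within a pixel of the border, where a naive
  kernel would lose clipped mass.  `truncate=None, renormalize=False`
  recovers the plain convolution form.
- Coincident annotations accumulate; nothing is deduplicated.
- Geometry-adaptive (k-NN) bandwidths used in some crowd-counting pipelines
  are deliberately out of scope; σ is fixed.

## Network

A fully convolutional encoder–decoder regresses the density map at full
input resolution:

- **Frontend** — the first 13 convolution layers of VGG-16.  Keeping all 13
  layers while producing features at 1/8 resolution requires retaining only
  the first three 2× max-poolings (after conv blocks 1–3) and dropping the
  later ones; the blocks 4–5 convolutions then run at 1/8 scale.
- **Multi-scale fusion** — three taps: F1 (after the second pooling,
  scale 4, 128 ch), F2 (frontend output, scale 8, 512 ch), and F3 derived
  from F2 by a 3×3 convolution plus 2× pooling (scale 16, 512 ch).  F1 is
  down-sampled and F3 up-sampled (bilinear, half-pixel centers) to F2's
  grid, the three are concatenated along channels and projected back to
  512 ch by a 1×1 convolution.
- **Attention** — a channel+spatial block: global average- and max-pooled
  channel vectors through a shared two-layer MLP (reduction 16, sigmoid)
  scale the channels; stacked channelwise mean/max maps through a 7×7
  convolution (sigmoid) scale the positions.  The block's hyperparameters
  follow the standard convention since the counting design specifies none.
- **Decoder** — five 3×3 convolutions with dilation 2 (widths
  512, 512, 512, 256, 128 — the five-layer reading of the architecture; a
  CSRNet-style sixth layer is intentionally not added), then a 1×1
  projection to one channel and bilinear 8× up-sampling *inside* the
  differentiable graph, so the network is trained against full-resolution
  targets and no count-rescaling factor is needed.
- Fusion and attention are independently toggleable, giving the four
  ablation variants (neither / multi-scale / attention / both).
- `width_multiplier` scales every channel count, enabling CPU-trainable
  miniatures of the identical topology (1/8 width ≈ 0.4M parameters vs
  ≈ 20M at full width).

Inputs are RGB in [0, 1], standardized with the ImageNet channel statistics
(the convention the VGG frontend was designed around).  Spatial dimensions
must be divisible by 8; `predict_count` reflect-pads other sizes and crops
the output back.

### Numerical backend

The environment targets plain scientific Python, so the network runs on a
compact reverse-mode automatic-differentiation core (`frycount.nn`) written
on numpy: broadcasted arithmetic, im2col convolution, 2×2 max pooling,
bilinear resampling, reductions and sigmoid/ReLU, with an SGD(momentum,
weight-decay) optimizer.  Every operator's backward pass is tested against
central finite differences; convolution and bilinear resampling are
additionally cross-checked against scipy.  Training tensors are float32;
density-map generation and metrics run in float64.

### Initialization

- The classical recipe (`init_weights`) draws backend convolution weights
  from N(0, 0.01²) with zero biases and expects a pretrained VGG frontend.
  Pretrained weights are only used when a local weight archive is supplied;
  nothing is downloaded.
- Training from scratch instead uses He initialization (the
  `ModelConfig.init="he"` default).  Two stability refinements matter at
  the reference optimizer settings (momentum 0.95 with tiny learning
  rates): decoder convolutions start at 0.7× the He scale, which lowers the
  curvature seen by the output head enough to stop momentum ringing without
  freezing learning, and the 1×1 output head always starts at N(0, 0.01²)
  so the initial prediction is near zero on the density scale (~10⁻² per
  pixel).
- A ReLU output activation is the config default; for from-scratch training
  the linear output (`output_activation="none"`, clamped non-negative at
  inference) is recommended and used by the package's own experiments: with
  a ReLU head the early optimization transient can push the shared
  pre-activation negative everywhere, after which the head is permanently
  dead.

## Objective and metrics

    L = LE + α·LSSIM,  α = 0.001

- `LE` is the summed squared pixel error, halved and averaged over the
  batch: `(1/2B) Σ_b ‖pred_b − gt_b‖²`.  The plain per-pixel mean is
  available (`euclidean_reduction="mean"`); the default convention is the
  one the reference learning rate of 1e-7 is calibrated against.
- `LSSIM = 1 − mean SSIM`, where SSIM is computed per pixel under an 11×11
  Gaussian window (σ_w = 1.5) over the valid region and averaged — the
  standard windowed protocol, applied to density maps with stabilizers
  c1 = 1e-4, c2 = 9e-4 (the usual (0.01·L)², (0.03·L)² with dynamic range
  L = 1, since the maps are on a [0, ~0.03] scale no range rescaling is
  attempted).  A global-statistics SSIM sits behind
  `ssim_windowed=False`.  The windowed implementation matches
  scikit-image's Gaussian-weighted SSIM to machine precision.
- Counting quality is MAE and RMSE over per-image (true, predicted) counts,
  with an optional breakdown over the four density levels
  Low [0, 249], Medium [250, 499], High [500, 749], Higher [750, 1000]
  (counts above 1000 fall into Higher).

## Training procedure

`TrainConfig` defaults encode the reference protocol: center crop to
768×576, 300 epochs, batch 10, SGD with learning rate 1e-7, momentum 0.95,
weight decay 5e-4, and two independent 50%-probability augmentations —
horizontal mirror and 180° rotation (the protocol's "mirroring and
flipping by 180 degrees" is ambiguous between one transform and two; both
are implemented, each individually toggleable).  Density maps are flipped
with the image as an array permutation, which is exact for every cell and
preserves the count bit-for-bit.  Validation MAE/RMSE are computed every
epoch from integrated counts; training runs the full epoch budget and
returns the best-validation-MAE weights (no early-stopping criterion is
defined by the protocol, so none is invented; an optional patience knob is
deliberately absent).  All randomness flows from one seeded generator, so
config + seed reproduce a run exactly.

The 1e-7 learning rate is faithful to the reference recipe but calibrated
for a pretrained, full-width network; the package's CPU-scale experiments
scale it to 1e-6.

## Synthetic scenes

`render_scene` emulates the acquisition setting the method was designed
for: an LED-lit tank bottom photographed top-down through ~2 cm of water.
Concretely: a light background (level 0.75) with a soft radial vignette and
a faint green-blue tint, over which n ≤ 1000 larvae are composited as
quadratic-Bézier strokes (length 8–22 px, Gaussian cross-profile of width
1.5–3.5 px, random curvature and orientation, dark albedo 0.05–0.35), plus
additive Gaussian pixel noise (σ = 0.02) clipped to [0, 1].  The
annotation of each larva is its ink centroid — the symmetric choice, since
real labeling conventions (head vs center) vary.  Scene randomness comes
from a single per-call generator: identical specs give bit-identical
scenes.

`DatasetSpec` defaults reproduce the study's split design exactly — per
level (Low/Medium/High/Higher): 121/139/105/25 training, 21/15/14/13
validation, 55/11/19/18 test images (390/63/103 in total), with each
image's count drawn uniformly within its level's range.

`easy_benchmark` generates deliberately benign scenes (192×144 px, 5–40
well-separated high-contrast fry, low noise) for CPU-scale training tests.

What the generator does **not** model: water refraction and caustics,
shadows, specular highlights, biological texture, motion blur, and
animal-to-animal appearance variation.  Passing the synthetic experiments
therefore demonstrates that the label construction, architecture, losses
and optimization interact correctly — not that the trained miniature would
transfer to real tank imagery.

## Scaled-down experiment sizes

The package's own verification experiments are sized for a single CPU:
shape/gradient checks use 1/16-width models on 64–192 px inputs; the
count-recovery experiment trains the 1/8-width model on the easy benchmark
(80 scenes from one seeded stream: 48 train, 12 validation, 20 held out)
for up to 30 epochs at batch 6 and learning rate 1e-6.  Small batches are
preferred at this scale because the number of SGD steps, not the epoch
count, limits how far the regression slope recovers from its initial
attenuation.

## Known limitations

- Reported model-size/inference-time figures of the original system are
  not reproduced; they are hardware- and serialization-dependent.
- No geometry-adaptive kernels, box/polygon annotations, learning-rate
  schedules, mixed precision, or multi-device training.
- The numpy backend is single-threaded apart from BLAS matmul; full-width,
  full-resolution training is out of its intended scope.
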