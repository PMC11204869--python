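# Methods

## Problem setting

Single-image super-resolution (SR) at integer scale factors s ∈ {2, 3, 4}
under the standard bicubic-degradation protocol: the low-resolution input
I_LR is synthesized from a ground-truth high-resolution image I_HR by
bicubic downsampling, a network learns the LR→HR mapping, and quality is
scored by PSNR/SSIM against I_HR. The intended downstream use is
preprocessing for object-counting models on plant images, where counting
accuracy is scored by per-image MAE and RMSE.

## The bicubic operator

Both the degradation and the classical baseline use one resampler: the
separable Keys cubic kernel

    k(t) = (a+2)|t|³ − (a+3)|t|² + 1          for |t| ≤ 1
         = a(|t|³ − 5|t|² + 8|t| − 4)         for 1 < |t| < 2

with a = −0.5, center-aligned coordinates (output pixel i samples the
input at (i + 0.5)/zoom − 0.5), edge replication at boundaries, and — when
downsampling — the kernel dilated by the zoom factor (antialiasing). This
is the MATLAB-`imresize` convention that dominates SR benchmarks; an
`antialias=False` switch provides plain decimation-style bicubic for
sensitivity checks. Weights at every output position are renormalized to
sum to 1 (partition of unity), so constant images are fixed points. The
implementation agrees with a dense 2-D kernel-summation oracle to 1e-9
and with Pillow's float-mode resize to float32 precision away from the
border (where boundary conventions differ).

Whether a given benchmark's LR images were made with or without
antialiasing is often unstated in the literature; the operator keeps the
flag explicit so both conventions can be tested.

## Network architecture

PlantSR is a post-upsampling residual network operating at LR spatial
size:

* `H_SF0`: one 3×3 convolution, 3 → C channels (feature F0);
* `H_SF1`: m residual groups (feature F1);
* `H_DF`: n residual groups (feature F_DF);
* `H_UP`: conv C → C·s², pixel shuffle ×s, conv C → 3, applied to
  F0 + F1 + F_DF.

A residual group (RG) is four Residual SE-attention Blocks followed by a
fusing 3×3 convolution and a group-level skip. The fusing convolution —
the convention of channel-attention residual networks — makes a
zero-weight group an exact identity, which yields a useful structural
invariant: zeroing all group convolutions collapses the network to
`H_UP(3·F0)`, tested as such. An RSEB computes
`x + SE(conv(relu(conv(x))))`; SE is squeeze-and-excitation gating
(global average pool → linear C → C/r → ReLU → linear C/r → C → sigmoid →
channel-wise rescale, with biases). No batch normalization anywhere
(standard for the EDSR lineage of SR networks).

Default configuration: C = 64, r = 16, m = 2, and n = 4/8/12 for
s = 2/3/4 — depth grows with scale, mirroring how SR parameter budgets
typically scale. All of C, m, n, r are exposed in the YAML config; exact
published parameter counts exist only for the baselines (below), so
PlantSR's own count is checked against an analytic layer-sum oracle
rather than an external figure.

×3 and ×4 upsampling each use a single pixel-shuffle stage (s² channel
expansion); the 63-px training patch at ×3 is chosen to be divisible by 3.

**Padding.** All convolutions use edge-replicate "same" padding rather
than zero padding. Zero padding injects dark rings at image borders that
cost about 1 dB of PSNR on 96-px evaluation images and that classical
resamplers (which replicate edges) do not suffer; replicate padding makes
network and baseline boundary conventions consistent. A `pad_mode="zeros"`
option retains the plain convolution.

**Initialization.** Untrained networks are initialized to implement
classical interpolation (the bilinear-deconvolution/ICNR lineage): the
head extracts RGB/3 into the first three feature channels, every residual
group starts as the identity via its zero-initialized fusing convolution
(as in zero-init residual-branch schemes), the channel-expanding
convolution holds truncated Keys-cubic phase filters (the 3-tap
renormalized approximation to bicubic a 3×3 kernel can represent), and
the tail reads the shuffled channels back out. An untrained PlantSR
therefore scores within ~0.1 dB of the bicubic baseline, and training
refines an interpolator instead of first rediscovering the color mapping
— the decisive factor for useful short CPU training runs. Remaining
weights (RSEB internals, SE) keep seeded Kaiming-style random values;
they are silenced at initialization by the zeroed fusing convolutions but
receive gradients from the first step on. `init="random"` restores plain
random initialization.

## Baselines

Rebuilt at their published configurations so their well-known parameter
budgets pin down the harness:

| model | structure | parameters |
|---|---|---|
| SRCNN | 9-5-5 convs on RGB, 64/32 channels, pre-upsampling | 69,251 (0.069 M) |
| VDSR | 20 bias-free 3×3 convs at 64 ch, global residual, pre-upsampling | 667,008 (0.667 M) |
| EDSR | 16 residual blocks at 64 ch, pixel-shuffle tail | 1,369,859 (×2) / 1,554,499 (×3) / 1,517,571 (×4) |

VDSR's convolutions are bias-free — the convention of its widely used
reimplementations and the only 3-channel variant that reproduces the
0.667 M figure. SRCNN and VDSR operate on all three RGB channels (Y-only
variants would not match the budgets). Pre-upsampling models consume the
bicubic-interpolated LR image; the training loop handles both styles.

## Metrics

* PSNR = 10·log10(MAX²/MSE) with MAX = 255, computed in float over all
  pixels and channels of 8-bit images, no border cropping, no luminance
  conversion. MSE = 0 reports +inf. A BT.601 Y-channel helper and a
  border-shave helper exist for cross-paper comparisons but are not the
  default.
* SSIM with C1 = (0.01·255)², C2 = (0.03·255)². Default mode is the field
  standard: 11×11 Gaussian window (σ = 1.5), population (weighted-moment)
  statistics, valid windows averaged, channels averaged — verified
  against scikit-image to 1e-7. A `global` mode evaluates the formula
  once per channel over the whole image (its closed form on constant
  images is used as an exact test value).
* Counting MAE = (1/n)Σ|ŷᵢ−yᵢ| and RMSE = sqrt((1/n)Σ(ŷᵢ−yᵢ)²), read
  from per-image CSV records; RMSE ≥ MAE always (power-mean inequality,
  property-tested).

Whether benchmark tables are computed on full images or fixed-size crops
is often ambiguous; both paths exist (full-image evaluation is the
default, patch evaluation via `extract_patch`).

## Training protocol

Each batch draws 32 HR patches — 64×64 for s ∈ {2,4}, 63×63 for s = 3 —
uniformly over training images then positions (with replacement), applies
horizontal flips independently with probability 0.5, and synthesizes LR
patches by the antialiased bicubic operator. Adam (β = 0.9/0.999,
ε = 1e-8) minimizes the unit-float L1 loss at a fixed 1e-4 learning rate;
no decay schedule. Evaluation converts outputs to uint8 before scoring so
PSNR uses the 8-bit dynamic range. After every epoch the model is scored
on the evaluation set; the best-PSNR epoch is kept, ties resolved to the
earliest. `batches_per_epoch` is configurable — on the synthetic fixtures
an epoch is a few hundred batches, whereas a full photographic dataset
would use tens of thousands.

Fine-tuning is the same loop started from a checkpoint (scale must
match), with the parent checkpoint recorded as provenance — the
transfer-learning route for adapting a general plant model to close-up
apple or soybean imagery.

The sampling stream is bit-reproducible from (seed, manifest, config).

## Tiled inference

Large images are processed as overlapping LR-frame tiles (default 128 px,
overlap 16 px). Half the overlap is trimmed from every interior tile edge
before assembly — those output pixels are corrupted by the tile's own
boundary padding — and remaining overlaps are averaged. For purely
convolutional paths the result matches the untiled forward exactly away
from seams. One caveat is intrinsic to the architecture: SE attention
pools globally, so its gates differ between a tile and the full image and
multi-tile output deviates from the untiled forward by ~1e-4 in
unit-float terms — far below the 1/255 quantization step, but not zero.
Images that fit a single tile are bit-identical to the direct forward.

When an upscaled image feeds a detector whose post-processing merges
nearby point predictions within a pixel radius (k-d-tree cutoff), that
radius must scale linearly with the upscaling factor; the package
provides this rule (`scale_distance_cutoff`) rather than any detector
internals.

## Synthetic data

`gen_plant_texture` emulates the statistics SR training needs, not
botany: a sum of seeded random sinusoidal gratings with log-uniform
frequencies up to 0.45 cycles/px and ~1/√f amplitudes (venation-like
oscillation), thresholded ridge lines (sharp vein edges), a low-frequency
illumination gradient, and a green-dominant palette per pseudo-taxon.
More than 1% of AC spectral power lies above the half-Nyquist of a
×2-downsampled grid (FFT-tested), so bicubic downsampling genuinely
destroys information and the SR task is non-degenerate. Counting scenes
place non-overlapping shaded disks on a dimmed texture with known count
and centers.

What the generator does **not** emulate: real sensor noise, JPEG
artifacts, depth-of-field blur, object occlusion, or the morphology of
actual taxa. Passing tests on this data demonstrates that the operators,
the training loop, and the evaluation chain are correct — not that the
default network reaches photographic-benchmark quality; that requires
GPU-scale training on real plant images.

## Problem sizes and numerical choices

* The overfit smoke experiment (the package's end-to-end check) trains
  the small configuration C = 16, m = 1, n = 2, r = 4, s = 2 for 200
  steps of 32 patches on 8 synthetic 96×96 images and evaluates on those
  same images — an overfitting sanity check sized for minutes on one CPU.
* The engine computes in float32; metrics and the resampler in float64.
* uint8 ↔ unit-float conversion divides by 255 and rounds half away from
  zero on the way back (exact round trip on all 256 values).
* HR images are cropped top-left to a multiple of the scale before
  degradation (deterministic).
* Tie-breaks: best checkpoint → earliest epoch; manifest ordering →
  sorted paths.
* Degenerate inputs: 1×1 images pass through the shape contract;
  zero-size resize targets, out-of-bounds patches, empty manifests, empty
  record lists, and scale mismatches raise immediately.

## Known limitations

* CPU-only NumPy engine: throughput is orders of magnitude below a GPU
  framework; the default (C = 64) configurations are buildable and
  runnable but realistically trainable only at reduced depth/width.
* Short training gains are bounded by what is *locally inferable* from
  the LR image. On the synthetic fixtures the smoke experiment surpasses
  bicubic by roughly 0.4–0.5 dB (the `overfit_psnr_gain_db` quantity in
  `scripts/acceptance.py`) and plateaus there: the generator's
  random-phase gratings alias under downsampling, and a
  translation-invariant network cannot memorize per-image phase even when
  overfitting, so only the edge-like structure (ridges) is sharpened
  beyond the interpolator. Larger margins over bicubic require longer
  training and content whose high-frequency detail is predictable from
  context, as in real photographs.
* SE globality makes multi-tile inference approximate (see above).
* No blur/noise/compression degradation models, no RAW/TIFF/multispectral
  inputs, no perceptual metrics, no detector implementations.
* The truncated-cubic initialization slightly sharpens relative to true
  bicubic (3 taps vs 4); the gap (~0.1 dB) is absorbed within the first
  training steps.
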