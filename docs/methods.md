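# Methods

## Problem

Laryngoscopy frames are annotated by painting each anatomical structure or
lesion as a filled polygon in one of seven fully saturated colors (benign
tumor red `#FF0000`, subglottis yellow `#FFFF00`, right/left true vocal
cords green `#40FF00` / cyan `#00FFFF`, right/left false vocal cords
azure `#0080FF` / violet `#4000FF`, cancer magenta `#FF00FF`).  The package
trains a network to reproduce that color-coded mask from the photograph and
measures agreement pixel-by-pixel per color.  Because every class color has
S = V = 100% at a distinct hue, all decoding reduces to hue-band
classification in HSV space.

## Color codec

Hue is handled on the 0–179 integer scale (1 unit = 2°).  A pixel is
assigned to the class with the circularly nearest canonical hue when

* the distance is at most the band half-width (default 10 units = 20°, a
  40° total band),
* saturation and value clear configurable floors (default 64/255 each).

Nearest-center assignment is needed because fixed 40° bins would overlap
(L-TVC at 90 units and R-FVC at 105 units are only 15 apart); ties break
toward the lower class id.  8-bit pixels have rational hues that can land
exactly on a band edge, so the edge comparison carries a 1e-9 guard —
exact-edge pixels are inside the band, and no representable hue falls
between the edge and the guard.  The saturation/value floors exclude dark
and washed-out background; both floors and the half-width are exposed on
`HueBandRule`.

## Network

A five-level U-Net whose encoder doubles as the adversarial critic:

* **Encoder** — five stages of (strided 3×3 convolution → instance
  normalization → ReLU → residual unit F(x)+x), each halving H and W
  (inputs must be divisible by 32).  Instance normalization is load-bearing
  under weight clipping: clamping all critic weights to [−c, c] would
  otherwise shrink activations geometrically with depth, and per-channel
  renormalization restores the scale after every stage.
* **Encoder output unit** — two 1×1 channel-only convolutions (d6, d7) off
  the bottleneck; global average pooling turns them into one-dimensional
  vectors, projected affinely to the latent vector l7 (default 32-dim) and
  the auxiliary vector l8.  The heads are purely affine — no activation —
  so sigmoid/softmax live in the losses: a validity scalar (a learned
  dimension reduction of l7), auxiliary class logits with more nodes (9)
  than classes (7) so lesion-free "dummy" frames and a spare unknown
  category get their own nodes, and a single adversarial logit from l8.
* **Decoder** — five upsampling stages (nearest ×2 → 3×3 conv → instance
  norm → ReLU), each doubling H and W.  Every skip connection passes
  through a configurable number of residual units (default 2; 1 in the
  desk-scale preset) and an additive attention gate (1×1 convs; the gate
  bias starts at +2 so skips begin open) before concatenation and a fusing
  convolution.  The fifth stage pairs with the full-resolution input level:
  its skip features come from a stem convolution of the raw image.  The
  stem belongs to the generator group, so it is never clipped — this keeps
  one full-strength path from input color to output color, which proved
  decisive for learning all seven color modes in short runs.
* **Output** — a 3×3 convolution to three channels with a sigmoid, bounding
  the segmentation to [0,1] for MSE/SSIM comparison against color masks.
  Its bias is initialized to −2: masks are mostly black, and starting the
  output dark means early training refines lesions instead of first
  crushing the background (the usual rare-foreground initialization);
  learning the background by descent instead was observed to poison the
  optimizer's second moments and lock the output at black.

Parameter groups: the encoder stages, d6/d7 and all heads form the
discriminator (critic) set, clipped to [−c, c] after every critic update;
the stem, decoder stages (including skip residual units and attention
gates) and output convolution form the generator set, never clipped.

## Training scheme

One cycle per batch: `disc_frequency` critic substeps followed by
`gen_frequency` generator substeps (the clinical-scale default is 1:1; the
desk-scale preset uses 1 critic : 2 generator).

**Critic substep** (updates + clips the encoder-side set only):

* validity: BCE-with-logits pushing the dimension-reduced latent of clean
  images toward 1 and of Gaussian-noise-mixed images toward 0 (targets
  smoothed by ε);
* auxiliary classification: cross-entropy with label smoothing
  ((1−ε)·one-hot + ε/K, ε = 0.1) against the dominant lesion class of the
  mask, with lesion-free frames assigned the dedicated dummy class;
* latent consistency: mean squared difference between the latents of an
  image and its random-affine-distorted copy;
* adversarial: real images toward 1, the generator's synthesis toward 0
  (the synthesis cached from the previous generator substep is reused when
  shapes match, saving a decoder pass).

**Generator substep** (updates the decoder-side set, no clipping):

* reconstruction: α(epoch)·MSE + (1−α(epoch))·(1−SSIM) between the
  predicted segmentation and the color-coded ground truth.  α falls
  linearly from 1.0 at epoch 0 to a configurable floor at the final epoch
  (default 0.5; the desk-scale preset uses 0.85 — with a critic
  concurrently moving the encoder features under the decoder, a dominant
  SSIM term was observed to re-collapse the output to black, so SSIM acts
  as a refinement there);
* adversarial: the synthesis fed back through the encoder should score as
  real (BCE with the smoothed real target; a pure Wasserstein objective —
  raw critic score difference, no sigmoid — is available as
  `wasserstein_adversarial` for ablation).

SSIM uses a uniform 7×7 window with zero padding (k1 = 0.01, k2 = 0.03,
data range 1); identical images score exactly 1.  BCE-with-logits is the
stable form softplus(z) − z·t.

Optimizers default to RMSProp (lr 5e-5 for both groups at clinical scale,
the convention for clipping-based adversarial training); Adam is available
by config.  Validation MSE on the held-out split is computed every epoch
and drives checkpointing: `last.ckpt` is always overwritten, and the three
best epochs are kept as separate files with the metric in the filename.
Scalars (`mse_loss`, `validity`, per-step loss terms) go to a JSONL event
log and a per-epoch CSV; a progress sheet PNG per epoch shows
[ground truth | segmentation | overlay | input] rows.

## Synthetic scenes

The generator emulates the label format, not endoscopy appearance: a dark
vignette with a bright shaded "lumen" disk in warm mucosa tones, smooth
gradients and speckle; 2–3 lesion polygons (5–9 vertices, 4–12% of the
image area each) placed on a ring around the lumen, painted into the mask
in exact table colors and tinted into the image at blend weight 0.55 so the
mapping is learnable; 15% of frames are lesion-free dummies.  Lesion
classes are drawn with probabilities proportional to the average per-image
pixel mass each class carries in the published clinical evaluation tables
(TP+FN of the per-class rows: cancer ≈3,400 px and L-FVC ≈3,700 px
dominate; benign tumors ≈420 px are rare), rather than uniformly — the
clinical frames are heavily cancer-weighted, and a uniform draw both
misrepresents that balance and starves the rarer color modes of training
signal at desk scale.  The weights are exposed as
`SceneConfig.class_weights`.  Polygons are
rasterized with even-odd pixel-center tests (origin top-left, half-open
convention: an axis-aligned w×h rectangle covers exactly w·h pixels).
Every sample derives its RNG from (master seed, sample index), so datasets
are reproducible and order-independent.  The default canvas is 256×256;
384×256 mirrors the per-image pixel count implied by the published
confusion tables (cells sum to ≈98,304 = 384×256); the desk-scale preset
uses 96×96.

What the fixtures do not contain: camera noise and motion blur, specular
highlights, occlusion, inter-annotator boundary variation, class-dependent
texture.  Passing the desk-scale contracts therefore demonstrates that the
architecture, objectives and measurement stack function end-to-end — not
clinical-grade performance.

The two training corruptions also live here: `apply_random_affine`
(rotation ±15°, translation ±10%, shear ±5° by default, edge-replicated
padding, pivot at the image center) and `mix_gaussian_noise`, which blends
the image with a Gaussian noise field at weight min(σ/255, 1) so σ = 0 is
the identity and σ ≥ 255 is pure, information-free noise (the default
critic input for the fake validity target).

## Evaluation stack

Per image and class, pixel confusion cells TP/TN/FP/FN are counted from
hue-band classification of prediction and ground truth; they always sum to
H·W.  Aggregation follows the convention that reproduces the published
per-class tables from their own printed cells:

* precision, recall and accuracy are computed from the dataset-averaged
  cells (the printed F1 for the cancer row, 0.77, is inconsistent with the
  harmonic mean of the printed aggregate precision/recall, 0.81, which is
  evidence the published F1 was averaged per image);
* F1 (2TP/(2TP+FP+FN)), pixel IoU, bounding-box IoU and mAUC are per-image
  means over images where the class occurs in ground truth or prediction.

bbIoU takes the axis-aligned bounding boxes of the largest 8-connected
component of each mask.  mAUC is an explicitly documented stand-in for an
unspecified per-image AUC approximation: the band half-width applied to
the prediction is swept over a fixed grid (1–90 hue units), each width
gives an (FPR, TPR) point against the fixed ground truth, the curve is
anchored at (0,0) and completed at (1,1), and the trapezoidal area is
reported; an all-black prediction scores exactly 0.5, a perfect one ≈1.
Classes absent from an image's ground truth are flagged NaN and excluded
from the mAUC mean.

Per image, a 13-column prediction record is written: predicted class (the
class of the largest detected polygon), top-3 latent indexes, the latent
difference ‖z(x) − z(affine(x))‖ (the ambiguous "difference value" is
implemented as distortion sensitivity), sigmoid validity, the encoder
error (Frobenius norm of the difference of channel Gram matrices of the
bottleneck features of x and affine(x), normalized by element count),
number of detected colors, largest-polygon area / area ratio / centroid,
and the input path.  Outputs per run: the per-class metrics table CSV, the
prediction CSV, a JPG directory of input/output overlays and a PNG
directory of largest-polygon renderings, under a `<date>-<dataset>`
directory (the `DATE` and `DATASET` environment variables override the
naming).  Validity is reported mean ± standard deviation; the latent
top-index histogram is included in the summary.

## Desk-scale study conditions

The published results come from 8,171 clinical images on GPUs and are not
reproducible at desk scale.  The package's own study, used by the test
suite and the acceptance script, is fixed once: 200 synthetic 96×96 scenes
split 160/40, a slim network (encoder channels 8-12-16-24-32, d6/d7 48/32,
one residual unit per skip, 32-dim latent), 15 epochs, batch 10, RMSProp
with lr 1e-3 (generator) / 5e-4 (critic), frequencies 1 critic : 2
generator, clip c = 0.05, noise σ = 255, α floor 0.85.  On one CPU this
runs in a few minutes.  Its contracts: held-out MSE falls below the
first-epoch value, cancer-class pixel IoU on held-out scenes exceeds 0.3,
and mean sigmoid validity of clean frames exceeds that of noise-mixed
frames (open-set separation).

## Numerical choices and degenerate inputs

* Precision/recall/F1 return 0 (flagged) on degenerate denominators;
  accuracy on all-zero cells raises.
* IoU of two empty masks is defined as 0; mAUC without ground-truth
  support is NaN.
* Degenerate (zero-area) polygons rasterize to nothing with a warning.
* All network math is float32; gradient checks run against centered
  differences at norm-level tolerance 1e-2.
* Checkpoints are NumPy archives holding the state dict, the model config
  and the epoch/metric; training aborts save state to `last.ckpt` before
  re-raising.

## Known limitations

* The scenes are deliberately synthetic; no claim about clinical images is
  made or tested.
* mAUC is a stand-in definition; its absolute values are not comparable to
  the published column.
* The critic and generator share the encoder, so critic updates move the
  skip features under the decoder; the desk-scale preset compensates
  (instance norm, α floor, 1:2 frequency), but very long runs at other
  scales may need retuning.
* Single process, single CPU/GPU-free; no distributed training or mixed
  precision.
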