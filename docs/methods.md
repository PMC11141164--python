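# Methods

## Model

The segmentation network is a hybrid CNN–Transformer U-Net whose encoder
output and three skip connections pass through dual-attention (DA)
blocks.  The forward path is: backbone → (optional) encoder DA-block →
1×1 patch projection onto `grid² = (img_size/16)²` tokens + learned
position embeddings → pre-norm ViT blocks (LayerNorm → multi-head
self-attention → residual; LayerNorm → GELU MLP → residual; dropout 0.1
at full scale) → final LayerNorm → reshape to `hidden × grid × grid` →
3×3 conv to `head_channels` → four decoder stages (×2 bilinear
upsampling, skip concatenation at the first three, two 3×3
conv+BN+ReLU) → 3×3 segmentation head.  Output resolution always equals
input resolution; channel count equals `n_classes`.

### Dual-attention block

Input `x` with C channels is processed by two parallel branches at a
reduced width `mid = max(1, C // reduction)`:

* reduce: 3×3 conv (C → mid) + BatchNorm + ReLU;
* attention: position attention (PAM) in one branch, channel attention
  (CAM) in the other;
* refine: 3×3 conv (mid → mid) + BatchNorm + ReLU.

The branch outputs are summed and one 1×1 convolution (mid → C, with
bias) restores the channel count; optional dropout sits before it
(off by default).  PAM projects its input with three independent 1×1
convolutions that keep the full (reduced) channel count — no C/8
bottleneck on the query/key path — and computes a row-stochastic N×N
affinity by softmax over the pairwise dot products; CAM uses the
row-softmaxed Gram matrix of the raw feature map with no convolutions.
Both softmaxes subtract the row maximum before exponentiation, which is
algebraically a no-op but prevents overflow.  The residual gates α and β
are single scalars per module, initialized to zero: each attention
module starts as the identity and the gate magnitude is learned.

A consequence worth knowing: at exact initialization (α = 0) the PAM
value/query/key projections receive zero gradient — the gate blocks
their only path to the loss.  The gate itself receives gradient
immediately, so after the first optimizer step every parameter is live;
the test suite checks gradient completeness after one update for this
reason.

The kernel sizes, normalization and activation inside the block, and the
presence of a dropout slot, are this package's declared choices (the
block's published description says only "convolution"); they mirror the
scene-segmentation head the block descends from.

### Backbones

* `r50` — the full-scale hybrid: weight-standardized convolutions +
  GroupNorm(32), a 7×7/2 stem, 3×3/2 max-pool, and three pre-activation
  bottleneck stages of 3/4/9 units (channels 256/512/1024, mid
  64/128/256).  Skips are taken at 64 (1/2), 256 (1/4) and 512 (1/8)
  channels; the 1024-channel 1/16 map feeds the encoder DA-block and
  patch embedding.  This is the only encoder consistent with the
  published parameter accounting.
* `tiny` — the architectural narrative taken literally: three plain
  conv-BN-ReLU blocks, each halving size and doubling width (8/16/32
  channels from a 1-channel input), plus a fourth block to 64 channels
  at 1/16.  It exists so that training, ablation and end-to-end tests
  run in seconds on one CPU.

The encoder DA-block sits on the deepest backbone map immediately before
patch embedding; where exactly it sits relative to the 1/16 downsampling
was an open choice and "before patch embedding" is the declared one.
Skips are stored deepest-first throughout (512/256/64 at full scale) —
documented here and asserted in tests because silent mis-ordering is the
classic U-Net wiring bug.

### Parameter accounting

With every DA flag off the model is the TransUNet baseline.  The
baseline configuration used for accounting is the binary-segmentation
one (224×224 RGB input, patch 16, 2-class 3×3 head): it counts
105,276,066 trainable parameters, in exact agreement with the published
baseline figure — note that a 9-class head cannot reach that printed
number for any head kernel, because its parameter total is odd while
every non-head layer contributes an even count.  Enabling the four
DA-blocks (1024-channel encoder + 512/256/64 skips, reduction 16) adds
1,755,540 parameters (+1.67 %) under the block design described above.
The corresponding published total implies roughly 2.67 M added
parameters; an exhaustive enumeration of every unstated design choice
(kernel sizes, biases, normalization, query/key bottlenecks, one vs.
three output convolutions, reductions 1–32, extra placements) found no
principled variant that lands on that figure, so the reference
implementation evidently contains layers its description omits.  This
package implements the documented design and reports the count it
actually has.

## Losses and metrics

Soft Dice in the losses uses smoothing ε = 1e-5 in numerator and
denominator; probabilities are clipped only inside the logarithms
(at 1e-7) so exact 0/1 predictions are lossless.  The multi-class Dice
term averages over all K classes including background.  Hard metrics use
exact set counts.  Conventions, chosen where the literature is silent
and surfaced rather than hidden:

* a class absent from both masks scores Dice = IoU = 1.0 and is flagged
  `both_empty`;
* Hausdorff distances are undefined (NaN) when either side is empty and
  are excluded from means with a warning;
* boundaries are the mask minus its 8-connected erosion (a single pixel
  is its own boundary);
* HD95 is the maximum over the two directed 95th percentiles
  (linear-interpolation percentile);
* binary prediction thresholds the sigmoid at 0.5 with ties going to
  foreground.

Both full and robust Hausdorff are always computed side by side, since
published "HD" columns in this literature are sometimes one and
sometimes the other.

## Synthetic phantoms

The generator emulates the two dataset shapes the method targets:
binary "lesion" phantoms (1–3 random ellipses, intensity 0.8 on a 0.2
background, optional smooth texture, additive Gaussian noise σ = 0.03,
clipped to [0, 1]) and multi-label "organ" phantoms (K−1 disjoint
ellipses with distinct intensity bands, placed by rejection with a
bounded retry budget).  Masks are the generating geometry, so ground
truth is exact and a sufficiently expressive model can reach Dice ≈ 1 —
which is precisely what the capacity test exploits.  What the phantoms
do **not** model: anatomical shape priors, modality physics (CT
calibration, endoscopic specularities, X-ray projection), inter-rater
label noise, and class imbalance at clinical severity.  Passing tests on
phantoms therefore certify the machinery (shapes, gradients, losses,
metrics, reproducibility), not clinical performance.

Images are floats in [0, 1] in memory and 8-bit grayscale PNG on disk
(quantization ≤ 1/255); masks store raw integer labels.  The on-disk
layout is `root/{images,masks}/NNNN.png` with matching stems.

## Training protocol

Defaults: Adam, lr 1e-3, β₁ 0.9, weight decay 1e-4, batch 4, constant
learning rate — the published recipe for the 2-D binary datasets
("momentum 0.9" for Adam is read as β₁, since Adam has no classical
momentum knob).  A `synapse_preset` mirrors the multi-organ CT recipe:
SGD, lr 0.01, momentum 0.9, weight decay 1e-4, batch 24, poly decay
(power 0.9).  No augmentation by default.  The published protocol uses a
3:1 train/test split and no validation set; this package holds out the
25 % split for model selection (best-validation checkpoint retained) and
documents that as its own choice; `val_fraction = 0` validates on the
training set, which the overfit tests use.  Training aborts with a
diagnostic on a non-finite loss or non-finite activations.  Everything
is seeded: model initialization, batch order, dropout and the split
derive from the configured seed, so a rerun in the same environment is
bit-identical, and a saved checkpoint reproduces its evaluation exactly.

## Ablation harness

Three axes, each emitting one table: placement (encoder/skip DA toggled
independently, 4 rows), per-layer skip DA (none / each single layer /
all, 5 rows), and the reduction sweep (1, 2, 4, 8, 16, 32; 6 rows).
All variants in a run share the data split and initialization seed, so
rows differ only in architecture.  At desk scale the harness
demonstrates structure and determinism; ranking variants scientifically
would need the full-scale configuration and real data.

## Problem sizes

The shipped tests and examples run the tiny configuration (64×64 or
32×32 phantoms, 8-image datasets, ≤ 200 epochs with early stopping at
Dice 0.96, 1-epoch ablation variants).  These sizes are the package's
chosen demonstration scale: large enough for the capacity check to be
meaningful, small enough that the whole suite runs in about a minute on
one CPU.  The full-scale `r50` configuration is built and counted (and
can run forward passes in a few seconds) but is not trained here;
training it requires the external benchmark datasets and GPU-scale
compute, with optional warm starting through the pretrained-checkpoint
hook.

## Known limitations

* The numpy engine is single-threaded-ish and eager; it is meant for
  correctness and desk-scale experiments, not throughput.
* 2-D only; no volumetric attention or 3-D distances.
* The pretrained-weight hook loads this package's own `.npz` naming; it
  does not translate third-party checkpoint formats.
* The published parameter total for the DA-enabled model is not
  reproducible from its described architecture (see Parameter
  accounting); the baseline total is reproduced exactly.
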