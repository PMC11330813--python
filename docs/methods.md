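# Methods

## Model

The segmentation network is an encoder-decoder with four 2×2 max-pool
stages, channel widths doubling from a base of 16 (16, 32, 64, 128; bottleneck
256), single-channel input and a single sigmoid output channel. Each stage is
a double-conv block `f(x) = ReLU(BN(conv3×3)) × 2` with an additive shortcut
(`y = f(x) + x`, 1×1 conv + BN projection when widths differ). Decoding uses
learnable 2×2 transposed convolutions; skips are optionally refined by SFEM,
fused across scales by MCEM and gated by attention gates before
concatenation. The four switches (`use_residual`, `use_sfem`, `use_mcem`,
`use_ag`) span the full ablation lattice from a plain U-Net to the complete
model; parameter counts grow strictly monotonically along it.

Where the architecture leaves room for interpretation, the package fixes it
as follows and exposes nothing else:

* Channel widths, depth and pooling type are not uniquely determined by the
  published description; base 16 / depth 4 / max-pool is the standard U-Net
  scaling consistent with the published parameter-count magnitudes (the plain
  baseline comes out at 1.94 M, the full model at 4.78 M trainable
  parameters — close to, but not exactly, the published 1.97 M / 4.58 M,
  which evidently depend on implementation details the description does not
  pin down).
* Channel attention combines the shared-MLP outputs of the average- and
  max-pooled descriptors by element-wise **sum before a single sigmoid**
  (the standard CBAM form, and the one the prose describes); the printed
  alternative — sigmoid per branch, then sum — is available as
  `cam_printed_form=True` for comparison only, and its gains lie in (0, 2)
  rather than (0, 1).
* In SFEM the refinement attention sees the **whole concatenation**
  `[conv3×3(F12), F1, F2]` (4C channels), not just the fused map, so channel
  attention can weigh all parent scales. A final 1×1 conv + BN restores the
  input width; without it the module would emit 9C channels and the decoder
  widths would be unspecifiable. Fusion convs preserve their 2C input width.
  SFEM weights are independent per skip level.
* MCEM merges coarse context into finer levels by 1×1 channel projection,
  nearest ×2 upsampling and element-wise addition followed by a 3×3 conv
  (the FPN convention); the coarsest path passes through unchanged. MCEM
  consumes the (possibly SFEM-refined) skips of all four levels, placing the
  pipeline order encoder → SFEM → MCEM → attention gate → decoder.
* Attention gates use intermediate width `skip_channels / 2`
  (attention-U-Net convention); the sigmoid coefficient map multiplies the
  skip branch, the decoder feature acting as gating signal.
* SE and CBAM channel-MLPs use reduction 16 with a hidden floor of 4
  (narrow layers would otherwise collapse to width 1).
* Batch-norm follows every convolution before its ReLU; BN running
  statistics (momentum 0.9, ε = 1e-5) are used at inference.

## Numerical core

No deep-learning framework is used: `maresnet.nn` implements the layers with
explicit forward/backward passes in NHWC float32 (float64 available via
config, used by the finite-difference tests). Convolutions are computed as a
sum of per-tap GEMMs over shifted input slabs, which supports dilation
directly and avoids im2col buffers; 2×2/stride-2 transposed convolution
writes four independent phase grids; max-pool ties resolve to the first
occurrence. Gradients accumulate (`+=`) into parameters so shared weights
(the CBAM MLP applied to two pooled descriptors) receive both contributions.
Initialisation is He-normal from a `numpy` generator seeded by the model
config, making builds and forward passes bit-reproducible. Every layer and
the fully assembled network pass central-difference gradient checks at 1e-6
tolerance in float64.

## Training protocol

Adam (β₁ = 0.9, β₂ = 0.999, no schedule), Dice loss with smoothing ε = 1.0,
batch size 4, learning rate 0.001, epochs run to completion with no early
stopping; the best-validation-IoU and the last checkpoints are kept, and
training resumes exactly from the latter (optimizer state included). The
sample order is shuffled once per run from the training seed rather than per
epoch: at the package's dataset scales this costs nothing measurable and
makes every epoch's batch partition — hence the whole run — exactly
reproducible and resumable. The logged "accuracy" is plain pixel accuracy,
recorded for curve parity only and never used for selection. Binarisation
threshold 0.5. Prediction reflect-pads inputs to the next multiple of
2^depth and crops the output back.

Evaluation aggregates per-image metric means by default (the common table
convention); global pixel pooling, under which F1 is exactly the harmonic
mean of pooled precision and recall, is available as a switch.

## Synthetic data

The generator emulates the statistics that make lesion radiographs hard:
low-frequency textured background (Gaussian-filtered noise, scale 24 px,
sd 14 intensity units) with a directional intensity gradient (amplitude 25),
bright elliptical distractor structures that do **not** enter the mask
(default 3, so attention has something to suppress), and 1–3 dark lesions
built from rotated ellipses (radius 12–48 px, aspect 0.55–1, possibly
overlapping into irregular shapes). Lesions are darkened — cystic lesions
are radiolucent — by 20–50 % of the intensity scale with Gaussian-blurred
borders (σ 2–6 px); the mask is the exact pre-blur ellipse union, and every
mask pixel is strictly darker than the lesion-free render of the same
scene. Pixel noise sd 6; 8-bit output. An "easy" preset (contrast
0.4–0.55, blur σ 1–2, noise 4) is the regime for capability demonstrations.
Average lesion prevalence under defaults is a few percent of pixels,
matching the class-imbalance regime of the clinical task.

What the generator does *not* model: real bone trabeculation, teeth and
mandible anatomy, projection geometry, acquisition artefacts, or
inter-annotator mask noise. Passing tests therefore demonstrate that the
architecture, gradients, training loop and metrics are correct and that the
model can learn hypodense-blob segmentation end-to-end — not clinical-grade
performance on radiographs.

## Augmentation

One sampled geometric transform per copy, applied identically to image and
mask: horizontal flip (p = 0.5), rotation ±15°, isotropic scale 0.9–1.1,
translation ±10 %, and grid-based elastic deformation (coarse 32-px grid of
Gaussian displacements, magnitude 8 px, bilinearly upsampled) as the
realisation of "local stretching". Images resample bilinearly with reflect
padding; masks nearest-neighbour with zero padding and re-binarisation, so a
pure integer translation moves the mask exactly rigidly. Two copies per
original triple a dataset (the expansion regime of the reference layout).
Augmentation happens after splitting and copies inherit their source's
split, so no augmented view of a held-out image can reach training.

## Problem sizes

The test suite exercises oracle comparisons on ≤ 8×8 toy grids, shape
contracts at 64² and 256², and two training runs chosen as the package's
demonstration scale: an overfit run (8 easy 64² images, base width 8, 50
epochs) and the scaled-down protocol run (full model at base 16, 32 easy
128² images, batch 4, lr 0.001, at most 50 epochs, trained in resumable
10-epoch chunks until the Dice criterion is met, then scored on 8 held-out
images).

## Known limitations

* CPU-only and single-threaded by design of the numerical core; wall-clock
  is dominated by the per-tap GEMM convolutions.
* Binary output only; no boundary metrics (Hausdorff/ASSD); no multi-class
  or 3-D support.
* The published parameter totals are not exactly reproducible from the
  published architecture description (see Model above); the package reports
  its own exact counts.
* BN statistics at batch size 4 are noisy; eval-mode predictions right after
  very short trainings can lag train-mode quality until the running
  averages settle.
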