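# Methods

This note documents the models, conventions and design choices behind
`tinyseg`, including the points where the design was genuinely open and
what the synthetic benchmark does and does not establish.

## Problem setting

The target imagery is photographs of a granular background (beach sand
on a conveyor tray, 1440×1440 px, cropped to 512×512 tiles) containing
a handful of foreground particles 3–10 px in diameter.  Background
pixels outnumber foreground by more than 99:1.  Two consequences drive
everything else: the loss must reweight the classes or the network
collapses to the background; and evaluation must prioritize recall,
because the downstream purpose (physically removing the particles)
tolerates false positives far better than misses.

## Architectures

All five networks are expressed as DAGs of primitive nodes.  Shared
conventions:

* 3×3 convolutions with "same" zero padding and stride 1; biases
  everywhere; no batch normalization.
* Downsampling by 2×2 max pooling, upsampling by 2× nearest-neighbour
  interpolation (no transposed convolutions).
* A stage applies its convolutions and a single ReLU at the stage
  output; the first convolution of a plain two-conv stage is linear.
* Skip connections concatenate the encoder tensor first, the upsampled
  decoder tensor second.
* Output head: 1×1 convolution to one channel, sigmoid.

**Plain family.** U-net has encoder stages 0–4 (stage *i* > 0 pools
first, then two convolutions) and decoder stages 5–8
(upsample, concatenate the matching encoder output, two convolutions).
Half U-net keeps stages 0–1 and their decoder partners around a
channel-reduced bottleneck — the deep, low-resolution stages exist to
model large-scale context that 3–10 px objects do not have.

**MultiRes family.** Each stage is a MultiRes block (MRB): three
chained 3×3 ReLU convolutions with output widths `out/6`, `out/3`,
`out/2`, concatenated and summed with the block input through a
residual shortcut, then a stage ReLU.  When the block preserves its
channel count the shortcut is the identity — the pure residual form;
when a stage changes width the shortcut is a linear 1×1 projection (as
in the original MultiResUNet).  Skip connections pass through a
residual path (RP): exactly four repetitions of
`f(X) = relu(conv1(X)) + relu(conv3(X))`.  The repetition count is
fixed at four at every depth; configurations requesting anything else
are rejected.  Half and Quarter MultiResUNet retain the first two /
first one encoder blocks plus a strongly channel-reduced bottleneck.

### Channel-width tables and their calibration

The per-stage channel widths are data, not code: YAML tables under
`src/tinyseg/configs/`, overridable per call.  The packaged defaults
were *calibrated*, not transcribed: the published description of these
networks fixes the stage structure but distributes the width numbers
over architecture diagrams that are not machine-readable, while
publishing exact complexity totals (parameters to four decimals of a
million, FLOPs to a tenth of a billion, at 512×512).  We therefore
solved for integer width tables that reproduce both totals to printed
precision under the declared counting conventions, preferring tables
with the canonical shape (doubling early widths, monotone decoder,
MultiRes branch splits in exact sixths).  The solution is internally
coherent — Half/Quarter MultiResUNet share their first-block width (30)
with the full model, and their bottlenecks (120, 30) are reduced
versions of the full model's deepest block (1164) — but it is a
complexity-equivalent reconstruction, not a pixel-level transcription
of the original diagrams: other tables with the same totals exist, and
results that depend only on parameter/FLOP accounting are insensitive
to the choice while learned-behaviour results could differ.

A note on the channel-preserving reading of the MRB: taking the
identity shortcut literally everywhere forces every encoder stage to
keep the stem's channel count.  That reading is internally inconsistent
with the published totals (no single width satisfies the
parameter/FLOP ratios of the Half and Quarter variants simultaneously)
and with the description of the reduced bottleneck as having "fewer
channels", which is impossible when blocks cannot change width.  The
projection-when-needed rule above resolves this while preserving the
identity-shortcut behaviour wherever it is well defined.

### Complexity conventions

* Parameters: `k²·c_in·c_out + c_out` per convolution; nothing else
  holds weights.
* FLOPs (one forward pass): `2·k²·c_in` operations per convolution
  output element (`k²·c_in` multiplications, `k²·c_in − 1` summation
  additions, one bias addition); one addition per element of an
  element-wise `add` node; pooling, upsampling, concatenation and
  activations count zero.  The per-node CSV breakdown
  (`complexity_report`) makes any alternative convention auditable.
* Receptive field: the standard recursion `r ← r + (k−1)·j`,
  `j ← j·s`, maximum over merging branches, jump halved through
  upsampling.  This yields 200 px for U-net, 66 px for Half
  MultiResUNet and 28 px for Quarter MultiResUNet.  Published
  receptive-field figures for these networks (up to 38,000 px for
  MultiResUNet) do not follow from any standard recursion we know;
  we report the standard computation and note the discrepancy rather
  than reverse-engineer an unstated convention.

## Loss

Weighted binary cross-entropy.  For one mask with `P` pixels and `ΣY`
foreground pixels, `w_T = P/ΣY`, `w_F = P/(P−ΣY)` (undefined — an
error — for all-foreground or all-background masks; the training path
uses a unit background weight for particle-free crops, which the strict
`class_weights` API still rejects).  The per-pixel weighted
cross-entropies are summed over the image and averaged over the batch.
Weights are computed per ground-truth image, so a crop with a single
3-px particle weighs its ~7 foreground pixels ≈2300× each.  Predictions
are clamped to `[ε, 1−ε]`, ε = 1e-7; during training the sigmoid is
fused with the loss and evaluated on logits, which needs no clamp.

## Metrics

`recall = TP/(TP+FN)`, `precision = TP/(TP+FP)`,
`F1 = 2PR/(P+R)`, `mIoU = TP/(TP+FP+FN)`, `rw-F1 = F1·recall`,
`rw-mIoU = mIoU·recall`.  Conventions: precision is 0 when nothing is
predicted positive, F1 is 0 when precision and recall are both 0
(reproducing the all-zero rows of a collapsed model); recall is
undefined (error) without foreground ground truth.  Metrics are
aggregated over pooled confusion counts of the whole evaluation set
(micro-averaging) rather than averaged per image — the formulas are
defined on raw counts, and pooling keeps single-particle crops from
dominating through per-image ratios; per-image averaging can be had by
calling `metric_suite` per image.  The practicality bar used
throughout — rw-F1 > 0.40 and mIoU ≥ 0.25 — is the operating point
"all particles found at precision 0.25".

## Training

Adam with β₁ = 0.9, β₂ = 0.999, ε = 1e-7; learning rate
`1e-3 · 0.96^⌊step/800⌋` — a staircase, with one step per optimizer
update, constant within each 800-step window.  Default batch size 8.
A pixel is predicted foreground iff its sigmoid output strictly
exceeds 0.5.  Final-epoch weights are evaluated; validation metrics
are logged each epoch and may drive optional early stopping (stop
after `patience` epochs without rw-F1 improvement), but never weight
selection.  All randomness — initialization (Glorot-uniform kernels,
zero biases), data order, augmentation — flows from a single seeded
generator, and identical seeds give bit-identical histories.
Divergence (non-finite loss) aborts with a diagnostic rather than
continuing.

Gradients are reverse-mode over the same node graph the forward pass
executes.  Convolutions in both directions are evaluated as one BLAS
matrix product per kernel tap on the contiguous input, accumulated
into a border-padded buffer whose margin absorbs the zero-padding
cases; this keeps every strided memory access a long contiguous run,
which on one CPU core is several times faster than materialized-im2col
or sliding-window formulations of the same arithmetic.

Five-fold cross-validation: the shuffled index set is cut into five
near-equal disjoint test partitions; the remaining 80% is split 72/8
into train/validation.  The report table has one row per
(architecture, fold) plus per-architecture averages — six metrics per
row from pooled test confusion counts.

## Synthetic scenes

The photo dataset behind this problem is not distributable, so the
generator emulates its statistics: smoothed uniform noise as a granular
sand texture (granule scale ~1.2 px, mean grey 0.45, amplitude 0.13),
1–3 anti-aliased disk particles per 128×128 scene with diameters
uniform in [3, 10] px, randomly brighter or darker than the sand by
0.25–0.55 grey levels.  Particle draws that would push the foreground
fraction to the 1% budget are re-drawn, so every emitted scene
satisfies the class-imbalance premise; configurations that cannot meet
the budget at all are rejected.  Scenes are grayscale by default
(3-channel replication available), reproducible bit-for-bit from the
generator state.

What the generator does *not* emulate: specular highlights and colour
variation of real sand, motion blur, uneven illumination, particle
shape irregularity (fibres, films), occlusion by grains, and label
noise at particle boundaries.  Training results on these scenes
therefore demonstrate that the pipeline — architectures, loss,
optimizer, metrics — learns heavily imbalanced tiny-object
segmentation end-to-end, and that the smallest architecture suffices
for locally-distinguishable particles; they do not predict absolute
performance on real photographs, where the texture/particle separation
is harder.

At synthetic-benchmark scale (200 scenes of 128×128, ~10 minutes on
one CPU core for Quarter MultiResUNet with plateau early stopping
within the 50-epoch budget), held-out rw-F1 reaches ~0.7–0.8, far above
the 0.40 bar.

## Augmentation

Random horizontal/vertical flips, rotation uniform in ±45°,
translation uniform in ±20% of the image size per axis.  The image is
warped with linear interpolation and mean-pixel fill; the mask with
nearest-neighbour interpolation (preserving binarity for 3-px objects),
background fill, and re-binarization.  The fill value defaults to the
image's own mean; for dataset-level work it should be the training-split
mean, passed explicitly (`AugmentConfig.fill`), to avoid test leakage.

## Utilization analysis

For each convolution, a histogram of its kernel scalars (bias
excluded) over 101 uniform bins spanning `[−max|w|, +max|w|]`, tagged
with stage index and connection kind (`feature` for in-stage
convolutions, `skip` for residual-path and projection convolutions).
The *zero-concentration* of a layer is the fraction of its weights
within ±ε of zero, computed from the exact weights, not the binned
counts.  A stage is *underutilized* when the mean zero-concentration
of its feature convolutions exceeds a threshold; the suggested
reduction is the deepest family member whose retained encoder stages
are all utilized.  The defaults ε = 0.01 and threshold = 0.9 are
declared conventions that make a visual judgment ("the deep stages'
weights collapse to zero") reproducible; both are reported alongside
the verdicts, and weights that shrink without converging to zero
remain a fundamentally ambiguous case.

## Numerical and engineering notes

* float32 tensors and weights; losses and metrics accumulated in
  float64.
* Max-pool gradient routing breaks ties by the first maximal element
  of each 2×2 window.
* Degenerate inputs are errors, not silent conventions, except where a
  convention is documented above (precision/F1 zeros, unit background
  weight in training).
* Tiling uses stride = tile − overlap (412 px for 512-px tiles with
  100-px shared borders) with the final row/column snapped to the
  image edge, guaranteeing full coverage; reassembly by overwriting is
  exact because overlapping regions originate from the same source.
  Empty-mask crops are kept (the training loss handles them); the CLI
  generator records every crop in the manifest.
* Problem sizes in the test suite (16–128 px toy models, 200-scene
  benchmark) were chosen as the smallest instances that still
  exercise every code path and the learning behaviour; all expected
  values in tests come from hand arithmetic, closed forms, or
  brute-force scalar oracles implemented independently of the library
  code.
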