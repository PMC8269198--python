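# Methods

## Problem and scope

The package segments individual CD163-stained macrophages (brown, DAB
chromogen) on RGB tiles of liver tissue with a blue hematoxylin
counterstain, and measures per-cell morphometry (area in px/μm²) downstream.
The scientific crux is not foreground/background separation — color alone
nearly solves that — but *instance* separation of adjacent and touching
cells.  Three strategies of increasing explicitness are implemented and
compared: vanilla semantic segmentation, semantic segmentation with
per-pixel loss weights, and pixel-embedding instance segmentation.

## Evaluation statistics

* **IoU** `|P∩T|/|P∪T|` on binarized masks, shared by all strategies (an
  instance prediction is binarized as the union of its instances).
* **SBD** — Symmetric Best Dice.  Best Dice averages, over the instances of
  one labeling, the best instance-wise Dice against the other labeling; it
  is not commutative (a labeling with spurious extra instances can still
  reach BD = 1 in one direction), so SBD takes the minimum of both
  directions.  Instance-wise Dice is computed on pixel sets via the joint
  label contingency table; a brute-force set-based implementation serves as
  the oracle in the test suite.
* Dataset aggregation: per-image values, reported as percent mean ±
  **sample** standard deviation (ddof = 1) across test images.  Which stdev
  convention the field uses is rarely stated; sample stdev was chosen and is
  used consistently.
* Empty-mask conventions (synthetic tiles may be empty; clinical tiles never
  were): both masks empty → 1.0, exactly one empty → 0.0, so perfect
  background prediction is not penalized.

## Per-pixel weight maps

A background pixel is a *gap* pixel when its Euclidean distances to the
nearest pixels of its two nearest distinct instances are both strictly below
`proximity_px` (default 10 px); gap pixels carry `gap_weight` (default 3.0,
"about thrice").  Foreground pixels 8-adjacent to background form the *edge*
band (depth 1 px, configurable) and carry `edge_weight` (default 0.5),
reflecting that hand-drawn contours are least reliable on the blurry cell
rim.  All other pixels carry `base_weight` (1.0).  Distances are Euclidean
(isotropy), computed with one exact distance transform per instance.  The
reduced edge penalty applies to foreground boundary pixels; applying it also
to the abutting background ring is available via `edge_side="both"`.  Cells
cut by the tile border are not treated as "edge" along the border.

## Networks

All families are built at configurable width (`base_channels`) and map an
RGB patch to full-resolution two-class scores:

* **UNet** — double-conv blocks, 2× max-pool encoder, skip-concatenating
  decoder.
* **SegNet** — same encoder topology without skips; decoding by nearest
  upsampling + convs (index-free unpooling stand-in).
* **DeepLab-v3 style** — strided stem to stride 4, residual body with
  dilations 1 and 2, a lite atrous pyramid (1×1, 3×3 dil 2, 3×3 dil 4,
  concatenated and projected), and a two-stage upsampling decoder.  Output
  stride 4 rather than 16: at tile sizes of 96–224 px and cell radii of
  8–40 px a deeper stride would discard most spatial detail.  The
  `mobilenetv2_style` backbone swaps the residual body for inverted-residual
  blocks (1×1 expand → 3×3 depthwise → 1×1 project).  No pretrained weights.

The **instance variant** duplicates the decoder: a structurally identical,
independently initialized second decoder reads the encoder features and
emits `embedding_dim` (default 8) channels per pixel.  Two deliberate
adaptations for the tiny CPU-scale variants:

1. **Coordinate channels to the embedding decoder.**  Two channels with a
   fixed scale (1 unit = 64 input px) are concatenated to the embedding
   decoder's input — never to the semantic path, which therefore stays
   translation-covariant.  During training a random constant offset per
   sample (±0.5 units) prevents the branch from memorizing absolute
   positions; at inference the offset is zero.  The fixed pixel scale keeps
   the embedding geometry identical across patch and tile sizes.
2. **Detached embedding gradients.**  Gradients from the embedding branch
   stop at the shared encoder.  At 16-channel encoder width the two
   objectives otherwise compete destructively (semantic IoU dropped from
   ~0.86 to ~0.5 under joint gradients in development experiments); with the
   branch detached the semantic head trains exactly as in the vanilla
   strategy and the embedding decoder learns on top of the induced features.
   `ModelConfig(detach_embedding=False)` restores joint training for larger
   models.

## Losses and training

Pixel softmax cross-entropy everywhere; the weighted strategy multiplies
per-pixel CE by the weight map (mean over pixels, not weight-normalized, so
weights scale the loss).  The instance strategy adds the discriminative
pull/push loss with defaults δv = 0.5, δd = 1.5, α = β = 1, γ = 0.001
(margins satisfy δd > 2δv so clusters are separable); the loss is computed
on ground-truth instances during training, clustering happens only at
prediction time.  Patches without any instance contribute only CE.

Optimizer: Adam, lr 1e-4, halved whenever the monitored loss fails to
improve by a relative 1e-4 for 15 consecutive optimizer steps
(`lr_schedule_step` implements exactly this rule and is pure/testable).
With desk-scale stochastic batches the raw per-batch loss is noisy enough
that its running minimum is set by noise dips and essentially never beaten,
which cascades the learning rate to zero within a few hundred iterations.
The training loop therefore (a) feeds the detector an exponential moving
average of the batch loss (factor 0.998), (b) keeps the detector off for the
first 100 iterations while the combined loss reorganizes, and (c) after each
reduction re-baselines the best to the current average and pauses the
detector for 75 iterations (the standard cooldown treatment).  All three are
`TrainConfig` fields.

Early stopping: validation loss (fixed, unaugmented patches) exceeding its
running best by 5 % on 10 consecutive checks; the returned weights are the
best-validation checkpoint.  Batch size default 8 (2 in the desk-scale
experiments), patch size default 224 (96 at desk scale).  Everything is
driven by one seed; identical seeds give bit-identical training curves.

## Augmentation and splitting

Geometric transforms (rotation at any angle; scaling, shear, warp with
factors from (0.8, 1.3)) are applied congruently: bilinear for image and
weight map, nearest for labels (no fractional instance ids); reflect-padding
for the image, zero (background) for labels.  Photometric jitter (per-channel
color, contrast, hue, exposure; ±10 %, hue ±0.05) touches only the image.
Each enabled transform fires independently with probability 0.5.  A draw
that removes every instance is retried up to 5 times, then returned with a
warning.  The elastic warp uses a Gaussian-smoothed displacement field
(σ = 12 px) with amplitude tied to the morphological factor range.

Datasets split at the patient level, 70/15/15; validation and test receive
`round(fraction · n_patients)` patients each, the remainder trains.  The
experiment runner enforces patient disjointness and evaluates only the
held-out test patients.

## Instance extraction

Semantic outputs: threshold 0.5 on foreground probability, 8-connected
components, minimum instance size 10 px (speckle filter; both configurable).
Instance outputs: mean shift over the embeddings of predicted-foreground
pixels.  The default bandwidth is `(δv + δd)/2 = 1.0`: the pull margin δv
bounds the cluster radius only at zero training loss, while the push margin
guarantees centroid separation ≥ 2δd, so the midpoint is the max-margin flat
kernel radius; `bandwidth=δv` remains one parameter away.  For large
foregrounds the fit runs on a seeded 3000-pixel subsample and remaining
pixels join the nearest mode.  Because the loss is hinged, pixels at the
interface of touching cells can settle into a small intermediate mode; a
cluster that is subordinate in size (< 0.5× a larger cluster) and lies
within 2·bandwidth of that cluster's centroid is merged into it.  Genuine
cells are unaffected: their trained centroids separate beyond the margin
band.  Clusters are instances regardless of spatial connectivity.

Tiles larger than the inference patch are processed by overlapped tiling
(default overlap 32 px) with triangular center-weighted blending of class
scores and embeddings, then extracted once on the stitched maps.  When a
tile fits in one pass (all desk-scale experiments) a single full-tile
forward is used; blending embeddings across patches is only approximate for
coordinate-informed embedding heads, a known limitation for very large
tiles.

## Synthetic data generator

Each cell is a rotated ellipse (aspect 0.75–1.0) whose boundary radius is
perturbed by a truncated Fourier series (harmonics 2–5, amplitudes ≤ 0.09) —
irregular borders; cells over 400 px receive 2–5 lighter interior spots
(foamy cytoplasm); every cell carries a darker rim (~35 % at the boundary)
so adjacent cells show a faint interface.  Rendering composites per-cell
alpha masks blurred with σ = 1.5 px (blurry edges) over a background of
tinted hematoxylin tone with darker nucleus-like blobs, plus Gaussian pixel
noise (σ = 0.02).  The label mask records the crisp generating silhouettes
exactly; overlapping placements are clipped so instances never share pixels.

A configurable fraction of cells (default 0.5, reflecting how often TAMs lie
adjacent in tissue) is placed as pairs with silhouette gaps drawn from
overlap-clipped (touching) up to ~2 px — covering both the regime only
instance labels can separate and the thin corridors the gap penalty fights
for; all other cells keep ≥ `min_gap_px` (6) background pixels.  Patient
structure: per-patient jitter of cell density (±25 %) and stain tone shared
by that patient's tiles.  All randomness flows from one seed through spawned
generators; infeasibly crowded draws retry with derived sub-seeds and a
reduced cell count before erroring.

What the generator does **not** emulate: out-of-focus regions, necrosis,
vessels and tissue tears, stain bleed-through, scanner color profiles, and
cells whose interface shows no intensity cue at all.  Passing tests on this
data therefore demonstrate that the pipeline's machinery (losses, weight
maps, embedding clustering, evaluation) behaves as designed — not clinical
performance.

## Desk-scale study conditions

The acceptance computation trains the DeepLab-style family
(`base_channels=8`, `embedding_dim=8`, ~17k parameters) on a synthetic
cohort of 67 patients × 3 tiles of 128×128 (≈ 200 tiles; 7 cells/tile,
radii 8–16 px): batch 2, patch 96, 1500 iterations for the semantic
strategies and 2500 for the instance strategy — the sizes at which each
strategy's validation loss has flattened on this cohort.  Observed behavior
mirrors the motivating study qualitatively: the instance strategy scores
highest on both IoU and SBD, weighted semantic buys a few SBD points over
vanilla at a small IoU cost, and ground-truth touching pairs that vanilla
fuses into one component are returned as two instances by the embedding
pipeline.  Absolute clinical values are out of reach by construction — the
cohort is synthetic and the models are ~100× smaller than production ones.

## Known limitations

* The NumPy engine is single-threaded and define-by-run; it is sized for
  tiny research models, not production training.
* SegNet uses upsample+conv decoding rather than true max-unpooling with
  stored indices.
* Stitched embedding fields from coordinate-informed heads are only
  approximately consistent across patches (see above).
* The generator's touching-pair interfaces always carry a faint rim cue;
  real confluent cells can be strictly ambiguous without shape priors.
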