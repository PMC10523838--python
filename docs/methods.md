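# Methods

## Problem setting

`somaswin` detects and segments neuronal cell bodies (somas) in 2D images
derived from two-photon Z-stacks of thick acute brain slices.  The imaging
regime is hard for contrast-based detectors: somas expressing a
calcium-sensitive fluorophore (GCaMP6s) change brightness with activity,
the surrounding neuropil contributes a dense low-contrast background, and
slices are imaged across many depth planes.  The package covers the whole
experimental loop: synthetic training-data generation, stack
preprocessing, a hierarchical shifted-window transformer segmenter, and a
quantitative evaluation protocol.

## Preprocessing

A Z-series (512x512 px, 2 um steps in the targeted acquisitions) is
reduced to network inputs in four steps, in order:

1. **Background subtraction** per slice.  No specific algorithm is
   attached to this step in the imaging literature we follow, so the
   package uses a grey morphological opening with a disc structuring
   element (the classic rolling-ball analogue), default radius 50 px, the
   common ImageJ default.  The exact disc is used up to radius 12; beyond
   that a decomposed (sequence) approximation keeps the cost linear.
2. **Median filter**, disc footprint, default radius 2 px, reflected
   edges.
3. **Maximum-intensity projection (MIP)** over consecutive windows of 10
   slices (20 um at 2 um steps), so each soma contributes its maximal
   cross-section.  A trailing partial window is kept and flagged, never
   silently dropped.
4. **CLAHE** on each projection, default clip limit 0.01 with an 8x8 tile
   grid, output in [0, 1].

Whether the first two steps run per slice or per projection is
configurable; the default is per slice, then project, then CLAHE, which
matches the order the steps are usually listed in imaging protocols.

## Synthetic data generation

Exhaustive manual annotation of somas is impractical, so training data is
composed: annotated soma crops are cut, pasted and blended into synthetic
backgrounds assembled from neuropil tiles.

* **Backgrounds.**  Tiles are shuffled and placed on a raster whose step
  is slightly smaller than a tile, each contribution weighted by an edge
  ramp; dividing by the accumulated weight makes the per-pixel blend
  weights sum to one, so seams are continuous and a set of identical
  tiles reproduces itself exactly.
* **Cells.**  Real annotated crops can be supplied; the default bank is a
  parametric renderer producing elliptical somas with a Gaussian-type
  falloff in normalised elliptical radius, scaled to cross the mask
  threshold (30 % of peak) exactly at the nominal boundary, plus mild
  multiplicative texture.  Peak intensity is drawn per perfusion
  condition — baseline aCSF [0.3, 0.6], NMDA [0.6, 1.0], washout
  [0.45, 0.8] — reproducing the low / high / mid-high fluorescence
  regimes; the neuropil mean (0.18) sits below the baseline regime.
  These regime values are this package's defaults for realistic contrast,
  not measurements.
* **Pasting.**  Placement offsets are uniform; a placement is resampled
  when its mask IOU with an already-placed instance exceeds
  `max_pairwise_overlap_iou` (default 0.1; 50 retries, then the cell is
  skipped and the skip recorded).  An optional `min_separation_px`
  enforces a clear gap between instances.  Compositing uses feathered
  alpha derived from the signed distance to the mask boundary (alpha 1
  inside the mask eroded by the feather width, 0 beyond the equally
  dilated boundary; default feather 3 px).  Poisson blending was
  considered and rejected: the feathered alpha is deterministic, cheap,
  and visually adequate at these contrasts.
* **Noise.**  Salt-and-pepper corruption replaces each pixel by 0 or 1
  (equal odds) with the configured density, for robustness experiments.
* **Determinism.**  One master seed; per-image child seeds come from
  `numpy.random.SeedSequence`, so a dataset is byte-reproducible from its
  config.  Default density is 5-20 cells per 512x512 image.

What the generator does **not** model: motion artifacts, photobleaching,
depth-dependent scattering, overlapping somas from different depth
planes, and dendrites/axons attached to somas.  Tests passing on this
synthetic family therefore demonstrate correctness of the machinery and
learnability of bright-blob segmentation, not field performance on real
slices.

## Backbone

The backbone is a four-stage hierarchical shifted-window (Swin)
transformer, implemented from scratch on a small reverse-mode autograd
engine over NumPy arrays (`somaswin.autograd`), so the identical code
path serves inference and training and the whole model runs on one CPU.

* 4x4 non-overlapping patch tokenisation (token dim 16 for grayscale),
  linear embedding to C = 96 channels (the small configuration).
* Blocks alternate W-MSA and SW-MSA: LayerNorm, windowed multi-head
  self-attention (M = 7 by default), residual, LayerNorm, two-layer MLP
  with GELU (expansion 4), residual.  Shifted blocks roll the grid by
  floor(M/2) before partitioning; an additive mask (-1e9 logits) keeps
  tokens that were not neighbours before the roll — and any zero-padding
  cells — from attending to each other, which makes the masked softmax
  weights exactly zero in float32.
* Learned relative position bias per head is included by default and
  switchable, since published descriptions of this backbone family
  usually carry it.
* Patch merging concatenates 2x2 neighbours (4C) and projects to 2C,
  halving resolution, so stages live at H/4, H/8, H/16, H/32 with
  channels C, 2C, 4C, 8C.
* Numerical choices: odd grids are zero-padded right/bottom before
  merging or windowing; windows are clamped to the grid when the grid is
  smaller than M, and the shift is dropped when a single window covers
  the grid; parameters are float32, truncated-normal init (sd 0.02)
  driven by an explicit seed.
* Stage depths default to [2, 2, 6, 2] with heads [3, 6, 12, 24] (head
  dim 32); [2, 2, 2, 2] is available — the exact depths of the original
  soma-segmentation configuration are not recoverable, so both are
  exposed and logged.

## Detection head and training

The head is deliberately proposal-free: lateral linear projections bring
each stage to a common width (default 64), nearest-neighbour upsampling
aligns them on the stage-1 grid, the sum passes through LayerNorm + GELU,
and a final linear layer emits a 4x4 patch of foreground logits per
token, restoring pixel resolution.  Instances are connected components of
the thresholded foreground probability (default 0.5, minimum area 8 px),
and each instance's confidence is its mean foreground probability.  This
makes confidence thresholding a transparent monotone filter: predictions
at a higher threshold are always a subset of those at a lower one.  The
default operating threshold is 0.05, favouring recall; it is exposed
everywhere as `--threshold`.

Training minimises pixel-wise binary cross-entropy against the union of
instance masks with a positive-class weight (default 4) countering the
sparse foreground, using AdamW (lr 1e-3, cosine decay to 10 %, weight
decay 1e-4).  Flips and optional salt-and-pepper corruption augment each
image.  Losses are logged per step; a non-finite loss aborts with a
diagnostic rather than training on.  Checkpoints embed the full
configuration and restore bit-identical predictions.

Known limitation: connected components cannot split two somas whose
predicted foreground touches, so adjacent cells can merge into a doublet
(counted as a false positive by the evaluation protocol); a
marker-based splitting step would be the natural extension.

## Evaluation protocol

* Dice = 2|X∩Y| / (|X|+|Y|), IOU = |X∩Y| / |X∪Y|; both error on two empty
  masks instead of returning a silent zero, and satisfy
  Dice = 2·IOU/(1+IOU) exactly.
* **Matching:** per ground truth, the candidate is the unassigned
  prediction with the highest Dice; the pair is a true positive only when
  its IOU exceeds 0.5, otherwise the ground truth is a miss and the
  candidate stays available.  Ground truths are processed in descending
  best-Dice order (ties by index), making contention resolution
  deterministic; assignment is one-to-one.
* **FP sub-types:** an unmatched prediction is *wrong-boundary* when its
  best IOU with any ground truth lies in (0, 0.5], *doublet* when it
  overlaps at least two ground truths each with IOU > 0.2, else
  *background*; wrong-boundary takes precedence when both rules apply.
  The 0.2 doublet threshold is this package's documented choice, as
  published tables categorise false positives only verbally.
* Precision TP/(TP+FP), recall TP/(TP+FN), yield rate = correct
  detections / ground-truth count; zero denominators raise rather than
  report 0.  Reports round precision/recall to 2 dp and percentages to
  1 dp.
* Somatic areas are pixel counts scaled by the squared pixel size (um/px
  must be supplied; it is acquisition-specific).  Area agreement reports
  mean and SD of (predicted − manual), the OLS slope/intercept of
  predicted on manual, and squared Pearson correlation, with NaN when the
  manual areas are constant.
* Threshold sweeps re-filter by confidence and re-match at each
  threshold, tabulating total detections and the percentage of correct /
  wrong-boundary / background+doublet verdicts per row.

## Problem sizes used in the shipped checks

The automated checks run at desk scale on one CPU: the matching rule is
cross-validated against a brute-force pixel-loop replay on random
instance sets (up to 6x6 instances, 16x16 grids); window attention with a
window covering the whole grid is compared with a naive global
self-attention oracle (agreement within 1e-5); the learnability check
trains the small configuration (C = 32, depths [1,1,1,1], window 4) on 16
synthetic 64x64 images of well-separated bright somas and requires recall
of at least 0.8 at IOU > 0.5 on that fixture; dataset reproducibility is
checked byte-for-byte over regenerated datasets.  These sizes are the
package's own verification choices; larger runs use the same code paths.

## Scope limits

Headline accuracies reported for the original acquisitions (mean Dice
0.91, precision 0.83, recall 0.86) require those authors' test slices and
trained weights, neither of which is released; this package does not
claim to reproduce them, and instead verifies every computable piece of
the pipeline against oracles and published worked examples (the
precision/recall/yield arithmetic from printed detection counts).
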