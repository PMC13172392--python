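# Methods

## What the benchmark models

The object of study is the tissue-detection step of a computational
pathology pipeline and its downstream effect on slide-level grading.
Two detectors are compared on the same slides: a classical
Otsu-threshold-plus-morphology algorithm with one fixed ("uniform")
parameter set, and a trainable encoder–decoder segmentation network.
All segmentation happens at 8.0 µm/px, heavily downsampled from the
slide's base resolution; masks are strictly binary. Downstream grading
consumes 256 × 256 px tiles at 1.0 µm/px that pass a ≥ 10 %
tissue-fraction rule evaluated on the mask.

## Synthetic slides

Real biopsy cohorts cannot ship with a package, so slides are generated
with exact planted ground truth. A slide is a pyramid with levels at
{1.0, 2.0, 4.0, 8.0} µm/px, built from the 1.0 µm/px render by
successive Lanczos downsampling (each level from the closest finer one,
never upsampled). Defaults: 1536 × 1536 µm, three tissue fragments of
characteristic scale 600 µm.

* **Fragments** are rotated ellipses (aspect ~0.3–0.5, as for elongated
  core-needle pieces) whose boundary radius is modulated by a low-order
  Fourier series (harmonics 2–5, amplitude σ = 0.04, clipped at ±0.35)
  — smooth, blob-like, controllable in area. Tissue truth at 8 µm/px is
  the area-majority (block mean ≥ 0.5) of the analytic indicator
  rasterized at 1 µm/px.
* **Color regimes.** Normal tissue is an eosin/hematoxylin-like pink
  (mean RGB 205/140/185, noise σ 5) on a near-white background
  (246 ± 2). Pale tissue (242/237/241, σ 2.5) keeps its mean luminance
  within `PALE_DELTA = 8` of background — the washed-out regime on
  which fixed thresholding parameters fail. A `mixed` profile renders
  one normal fragment and pale ones, with the lesion planted in a pale
  fragment; this is the "missed fragment" fixture in which a luminance
  thresholder finds some tissue (so the slide is not excluded) while
  missing the lesion entirely.
* **Lesions** are inner level-sets of one fragment's radial coordinate,
  sized to a target fraction (default 25 %) of total tissue area;
  lesion truth is pixel-wise contained in tissue truth and carries an
  ISUP grade 1–5.
* **Artifacts** are drawn only outside tissue and labelled background:
  pen marks as thick saturated polyline strokes (60 µm wide), debris as
  dark specks of 4–12 µm radius. They exist to make precision penalties
  and artifact-only masks measurable.
* **Reproducibility.** Every slide draws from one generator stream
  seeded by `(seed, crc32(slide_id))`, so cohorts reproduce slide by
  slide regardless of generation order.

Measured on the default geometry, tissue occupies roughly 10–30 % of a
slide; the tests assert the configured band (3–45 %) over 50 seeded
slides. The generator makes no attempt at photorealistic H&E texture,
stain deconvolution, or scanner-specific color: passing tests show that
the pipeline and statistics behave correctly under the modelled
contrasts, not that either detector would reach these numbers on real
scanner output.

## Classical detector

Pipeline at 8 µm/px: channel transform → Gaussian blur (σ = 1 px) →
256-bin histogram → Otsu's threshold (maximize between-class variance
over all 255 cuts; ties to the smallest level) → binary mask → closing
(disk r = 1) → opening (disk r = 1) → remove objects < 32 px → fill
holes < 64 px. A histogram with all mass in one bin admits no cut; the
pipeline then returns an empty mask with no exception, since a
detection failure is a tallied outcome, not an error.

Two channel transforms are provided because the optimal choice depends
on stain character: inverted BT.601 luminance (default; tissue darker
than background) and HSV-style saturation (pale, eosin-only tissue
separates better in chroma). Neither is claimed to match any particular
production implementation.

The `uniform` preset adds a contrast floor `min_channel_level = 20`:
nothing below that level in the transformed channel counts as tissue.
This models the fixed contrast assumption inherent in using one
parameter set for all slides — the floor is well below normal tissue
(inverted luminance ≈ 90) and well above background noise (≈ 9), but
pale tissue (≈ 14) falls under it, so pale slides yield empty masks.
Without such a floor Otsu always returns *some* cut and failure on
low-contrast slides would be accidental rather than a property of the
parameterization. Morphological cleanup is idempotent by construction
(verified by test).

## Trainable detector

A one-level U-shaped convolutional network implemented directly on
NumPy arrays with hand-coded backpropagation: two 3×3 conv blocks
(8 channels), 2× average-pool bottleneck (16 channels), nearest-
neighbour upsampling, skip concatenation, a 3×3 fusion conv and a 1×1
output head — about 4,000 parameters. Tissue/background discrimination
on these slides is dominated by local color and texture, so a small
receptive field suffices; the training *protocol* (loss, optimizer,
early stopping, tiling conventions), not network capacity, is the
object under test.

* **Inputs** are encoded as `(255 − v) / 64` per channel — an
  absorbance-like amplification. Raw `v/255` reflectance leaves the
  pale-tissue contrast (~0.02) too small for a from-scratch net to
  exploit within a short schedule; the encoding brings it to O(0.1)
  without changing the information content.
* **Loss**: pixel-wise binary cross entropy with logits, positive-class
  weight 5.0 (tissue is the minority class and missed tissue is the
  costly error).
* **Optimizer**: AdamW (decoupled weight decay 0.01, ε = 1e-6,
  β = 0.9/0.999). The recorded default learning rate is 1e-6 — the
  regime appropriate to fine-tuning a large pretrained backbone; the
  desk-scale schedule (`DESK_TRAIN_CONFIG`) overrides it to 6e-3 for
  the small from-scratch net, with 64-px tiles at 8 µm/px, batch 16, at
  most 60 epochs and patience 12.
* **Early stopping** on validation F1 computed over the global pixel
  pool (chosen over a per-tile mean, which would overweight
  near-empty tiles); the checkpoint with the best validation F1 is
  returned. `max_epochs = 0` returns the initial weights with their
  validation score, and fixed seeds make training bit-reproducible.
* **Augmentation** (defaults): horizontal/vertical flips, 90°
  rotations, mild per-channel gain/bias jitter (strength 0.1).
  Jitter strength is deliberately configurable: stronger color
  augmentation is the natural lever for robustness to unusual stain
  profiles.
* **Labels** for training are the generator's ground-truth masks,
  standing in for a curated high-quality mask set.

Inference mirror-pads the 8 µm/px raster so a whole number of tiles
fits (reflective padding split evenly, extra pixel to bottom/right,
original recoverable at the stored offset), predicts tiles at stride
`tile − 2·overlap` (overlap defaults to a quarter tile: 128 px for
512-px tiles, 16 px for the desk-scale 64-px tiles), and keeps only
each tile's central region — except image-border margins, which are
kept because no neighbouring context exists. Every output pixel is
written exactly once, and for a pixel-local model tiled inference
equals whole-image inference bit-exactly (both are tested invariants).
Probabilities are binarized at 0.5.

Model selection follows the sensitivity-first rule: among candidates
with precision ≥ 0.90, pick the best sensitivity; ties break to higher
precision, then lower index; no qualifying candidate is an error.

## Tiling for the downstream grader

Grading tiles (256 px at 1.0 µm/px) are laid on a grid anchored at the
slide origin, mirroring only past the far edges, so tile coordinates
remain aligned with the 8 µm/px mask grid (scale factor 8) and the
tissue fraction of a tile is the mean of its 32 × 32 mask window —
provably equal to the fraction computed on a nearest-neighbour
upsampled mask for aligned tiles (tested oracle). Training mode tiles
without overlap; inference mode uses "128 px shared with each
neighbour", i.e. a 64-px discarded margin per edge under the single
rule stride = tile − 2·overlap (an overlap ≥ half a tile would give a
non-positive stride and is rejected). Tiles with tissue fraction
≥ 0.10 (inclusive) are kept. Tile rasters come from the pyramid level
with the largest mpp not exceeding the target, Lanczos-resampled;
an exactly matching level is cropped bit-exactly.

## Downstream surrogate grader

The real grading model is deliberately replaced by a deterministic
function of lesion coverage: with `c` the fraction of lesion pixels (at
8 µm/px) under kept-tile footprints, the predicted grade is the true
ISUP label when `c ≥ 0.5`, one grade lower (floored at 1) when
`0.1 ≤ c < 0.5`, and benign (0) otherwise; benign slides always grade
0. The thresholds are chosen so the two canonical missed-tissue failure
patterns are reproduced: a fully missed lesion-bearing fragment gives a
benign call, a partially covered lesion gives a one-grade downgrade.
Because the surrogate is a pure function of the mask, any downstream
discordance isolates exactly the tissue-detection effect — no claim is
made that surrogate discordance *rates* match those of a real trained
grader.

The paired comparison protocol: segment every slide with both arms;
slides where either arm detects no tissue are excluded from grading and
tallied in the 2×2 paired failure table (A-only / B-only / both /
total); included slides are tiled per mask, graded per arm, and
aggregated into per-arm quadratic weighted kappas against the reference
grades (percentile bootstrap, 1000 replicates, resampling the declared
aggregation unit) and a discordance summary.

## Statistical choices

* "Exact binomial" confidence intervals are implemented as
  Clopper–Pearson (Beta-quantile) intervals; this reading is validated
  by reproducing both printed failure-rate intervals to all three
  printed decimals.
* McNemar's test defaults to the exact binomial form because the
  discordant counts of interest (2 vs 116) are far outside χ²
  asymptotic comfort; the continuity-corrected χ² variant is available
  and agrees on the < 1e-10 conclusion. `b = c = 0` returns p = 1 by
  convention.
* Quadratic weighted kappa is computed from the direct formula with the
  category set fixed to 0–5 by default; two equal constant vectors
  (zero expected disagreement) return 1 by convention. An independently
  implemented library version serves as a test oracle only.
* Bootstrap intervals use the percentile method (simplest standard
  choice for kappa CIs); replicates on which the statistic is undefined
  are redrawn and counted. All bootstrap output is bit-reproducible
  under a fixed seed.
* Direction-of-correctness counts in the discordance summary are
  restricted to malignant (reference ≥ 1) discordant slides, so the
  three directions always sum to the malignant discordant count.

## Problem sizes and degenerate inputs

The package's own experiments use 1536-µm slides, a training cohort of
10 slides plus 4 validation slides for the learned detector, and a
standard 30-slide evaluation cohort (normal/pale/artifact/empty mix
with planted lesions, one patient per slide); the full acceptance run
completes in a few minutes on one CPU. Degenerate inputs have defined
behaviour throughout: empty slides produce empty masks and count as
detection failures in both arms; empty predictions flag precision as
undefined and are excluded from precision aggregation; empty case lists,
zero-area slides, misaligned tile coordinates, non-positive strides and
histograms without two occupied bins raise typed errors.

## Known limitations

* The synthetic contrast regimes are caricatures: two (plus mixed)
  color profiles rather than the continuum of real scanner/stain
  variation; no blur, folds, coverslip edges, or marker-over-tissue.
* The learned detector is intentionally tiny and trained on ground
  truth labels; its near-ceiling metrics on this benchmark say nothing
  about large-backbone performance on real WSIs.
* The surrogate grader has no notion of pattern morphology; it cannot
  model grading errors that are not mask-induced.
* The exact morphology chain and parameter values of any particular
  production thresholding implementation are not reproduced; the chain
  here is a declared reference with every stage parameterized.
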