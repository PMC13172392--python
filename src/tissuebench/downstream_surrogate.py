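"""Deterministic surrogate for the downstream grading model.

The real grading model is a trained slide-level classifier; its exact
predictions are irrelevant to the question studied here, which is how
the *tissue mask* changes what the grader sees.  The surrogate therefore
grades purely from lesion coverage: the fraction of the planted lesion
that falls under kept-tile footprints.  Full coverage returns the true
grade, partial coverage drops the grade by one (never below 1), and
near-zero coverage returns benign — the two canonical failure patterns
of missed-tissue errors (total miss -> benign call, partial miss ->
one-grade downgrade).  Being a pure function of the mask, every
downstream statistic isolates exactly the tissue-detection effect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .core import GroundTruth, InvalidSpecError, SlidePyramid, TissueMask
from .comparison_stats import (
    DiscordanceSummary,
    FailureAnalysis,
    KappaResult,
    discordance,
    kappa_with_ci,
    paired_failure_analysis,
)
from .threshold_segmentation import is_detection_failure
from .tiling import TileSet, TilingConfig, tile_slide

Segmenter = Callable[[SlidePyramid], TissueMask]


@dataclass(frozen=True)
class SurrogateGraderConfig:
    full_coverage_threshold: float = 0.5
    partial_coverage_threshold: float = 0.1

    def validate(self) -> None:
        if not 0 < self.full_coverage_threshold <= 1:
            raise InvalidSpecError("full_coverage_threshold must be in (0, 1]")
        if not 0 < self.partial_coverage_threshold < self.full_coverage_threshold:
            raise InvalidSpecError(
                "partial_coverage_threshold must be in (0, full_coverage_threshold)")


def lesion_coverage(truth: GroundTruth, tiles: TileSet) -> float:
    """Fraction of lesion pixels (at mask resolution) under kept tiles."""
    lesion = truth.lesion_mask
    if not lesion.any():
        return 0.0
    s = tiles.config.scale_factor
    side = tiles.config.tile_size_px // s
    covered = np.zeros_like(lesion, dtype=bool)
    for rec in tiles.records:
        y0, x0 = rec.y // s, rec.x // s
        covered[y0:y0 + side, x0:x0 + side] = True
    return float(np.sum(covered & lesion) / lesion.sum())


def surrogate_grade(
    truth: GroundTruth, tiles: TileSet, config: SurrogateGraderConfig | None = None
) -> int:
    """Grade 0..5 from lesion coverage under the kept tiles."""
    if config is None:
        config = SurrogateGraderConfig()
    config.validate()
    if truth.isup_label == 0:
        return 0
    covered = lesion_coverage(truth, tiles)
    if covered >= config.full_coverage_threshold:
        return truth.isup_label
    if covered >= config.partial_coverage_threshold:
        return max(truth.isup_label - 1, 1)
    return 0


# ---------------------------------------------------------------------------
# End-to-end paired comparison


@dataclass
class SlideOutcome:
    slide_id: str
    ref_grade: int
    failed_a: bool
    failed_b: bool
    grade_a: int | None
    grade_b: int | None

    @property
    def included(self) -> bool:
        return not (self.failed_a or self.failed_b)


@dataclass
class GradingComparison:
    """Per-slide grades under both arms plus every aggregate statistic."""

    outcomes: list[SlideOutcome]
    failure_analysis: FailureAnalysis
    kappa_a: KappaResult | None
    kappa_b: KappaResult | None
    discordance: DiscordanceSummary | None

    @property
    def included(self) -> list[SlideOutcome]:
        return [o for o in self.outcomes if o.included]


def run_comparison(
    cohort: Sequence[tuple[SlidePyramid, GroundTruth]],
    segmenter_a: Segmenter,
    segmenter_b: Segmenter,
    tiling_config: TilingConfig | None = None,
    grader_config: SurrogateGraderConfig | None = None,
    replicates: int = 1000,
    seed: int = 0,
) -> GradingComparison:
    """Evaluate the downstream grader once per arm and compare.

    Each slide is segmented by both methods; slides where either arm
    fails to detect tissue are excluded from grading (and tallied in the
    paired failure table).  Included slides are tiled per mask, graded
    by the coverage surrogate, and aggregated into per-arm quadratic
    weighted kappas (bootstrap CIs) and a discordance summary.
    """
    if len(cohort) == 0:
        raise InvalidSpecError("cohort is empty")
    if tiling_config is None:
        tiling_config = TilingConfig()
    if grader_config is None:
        grader_config = SurrogateGraderConfig()

    outcomes = []
    fails_a: dict[str, bool] = {}
    fails_b: dict[str, bool] = {}
    for pyramid, truth in cohort:
        mask_a = segmenter_a(pyramid)
        mask_b = segmenter_b(pyramid)
        fa, fb = is_detection_failure(mask_a), is_detection_failure(mask_b)
        fails_a[pyramid.slide_id] = fa
        fails_b[pyramid.slide_id] = fb
        ga = gb = None
        if not (fa or fb):
            tiles_a = tile_slide(pyramid, mask_a, tiling_config, mode="infer")
            tiles_b = tile_slide(pyramid, mask_b, tiling_config, mode="infer")
            ga = surrogate_grade(truth, tiles_a, grader_config)
            gb = surrogate_grade(truth, tiles_b, grader_config)
        outcomes.append(SlideOutcome(pyramid.slide_id, truth.isup_label, fa, fb, ga, gb))

    fail = paired_failure_analysis(fails_a, fails_b)
    included = [o for o in outcomes if o.included]
    kappa_a = kappa_b = disc = None
    if len(included) >= 2:
        ref = [o.ref_grade for o in included]
        ga = [o.grade_a for o in included]
        gb = [o.grade_b for o in included]
        kappa_a = kappa_with_ci(ref, ga, replicates, seed, "slide")
        kappa_b = kappa_with_ci(ref, gb, replicates, seed, "slide")
        disc = discordance(ga, gb, ref)
    return GradingComparison(outcomes, fail, kappa_a, kappa_b, disc)
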