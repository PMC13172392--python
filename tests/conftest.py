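"""Shared fixtures: seeded synthetic slides, cohorts, and one trained
segmenter checkpoint reused across the suite (training is the expensive
step, so it runs once per session)."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import tissuebench as tb
from tissuebench.learned_segmentation import (
    DESK_TRAIN_CONFIG,
    AugmentationPolicy,
    make_training_tiles,
    train,
)


def make_slide(slide_id: str, seed: int = 7, **kwargs):
    return tb.generate_slide(tb.SyntheticSlideSpec(slide_id=slide_id, seed=seed, **kwargs))


def mixed_cohort(n: int, seed: int, prefix: str):
    """Normal/pale/artifact mix used for training and spot checks."""
    slides = []
    for i in range(n):
        profile = "pale" if i % 4 == 3 else "normal"
        arts = frozenset()
        if i % 5 == 4:
            arts = frozenset({"pen_mark"})
        elif i % 7 == 6:
            arts = frozenset({"debris"})
        slides.append(make_slide(f"{prefix}{i:02d}", seed=seed,
                                 color_profile=profile, artifacts=arts,
                                 patient_id=f"{prefix}pat{i:02d}"))
    return slides


@pytest.fixture(scope="session")
def normal_slide():
    return make_slide("fix_normal", seed=7)


@pytest.fixture(scope="session")
def pale_slide():
    return make_slide("fix_pale", seed=7, color_profile="pale")


@pytest.fixture(scope="session")
def blank_slide():
    return make_slide("fix_blank", seed=7, n_fragments=0)


@pytest.fixture(scope="session")
def small_cohort():
    """Ten slides, mixed profiles, for module-level checks."""
    return mixed_cohort(10, seed=33, prefix="sc")


@pytest.fixture(scope="session")
def eval_cohort():
    """The standard seeded evaluation cohort: 30 slides with normal,
    pale, artifact-bearing, and empty slides plus planted lesions."""
    specs = tb.cohort_specs(30, seed=101, prefix="ev")
    return [(spec, *tb.generate_slide(spec)) for spec in specs]


@pytest.fixture(scope="session")
def trained_checkpoint():
    """Desk-scale segmenter trained on a cohort disjoint from evaluation."""
    train_slides = mixed_cohort(10, seed=21, prefix="tr")
    val_slides = mixed_cohort(4, seed=22, prefix="va")
    cfg = dataclasses.replace(DESK_TRAIN_CONFIG, seed=0)
    ck = train(
        make_training_tiles(train_slides, cfg.tile_size_px),
        make_training_tiles(val_slides, cfg.tile_size_px),
        cfg,
        AugmentationPolicy(),
    )
    assert ck.val_f1 > 0.9, "training failed to converge"
    return ck
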