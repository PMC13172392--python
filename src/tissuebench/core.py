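"""Shared domain objects for the tissue-detection benchmark.

The unit of analysis is a pyramidal RGB slide raster with per-level
microns-per-pixel (mpp) metadata.  Segmentation masks live at a coarse
working resolution (8.0 µm/px by default) and are strictly binary; each
mask records which method produced it so that downstream accounting can
pair the two arms of the comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Working resolution of all tissue masks, in microns per pixel.
MASK_MPP: float = 8.0

#: Mask provenance labels.
MASK_METHODS = ("threshold", "learned", "truth")

# ITU-R BT.601 luma coefficients, used for every grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


class TissueBenchError(Exception):
    """Base class for package errors."""


class InvalidSpecError(TissueBenchError):
    """A slide or configuration specification violates its invariants."""


class DegenerateHistogramError(TissueBenchError):
    """All histogram mass sits in a single bin; no threshold exists."""


class NoQualifyingModelError(TissueBenchError):
    """No candidate model meets the precision floor."""


class IntegrityError(TissueBenchError):
    """A persisted artifact fails its round-trip integrity checks."""


def luminance(rgb: np.ndarray) -> np.ndarray:
    """BT.601 luma of an (..., 3) RGB array, as float64 in [0, 255]."""
    rgb = np.asarray(rgb, dtype=np.float64)
    return rgb @ _LUMA


def level_dims(level0_dims: tuple[int, int], base_mpp: float, mpp: float) -> tuple[int, int]:
    """Raster dims (h, w) of a pyramid level, ceil-scaled from level 0."""
    scale = mpp / base_mpp
    return (int(np.ceil(level0_dims[0] / scale)), int(np.ceil(level0_dims[1] / scale)))


@dataclass
class SlidePyramid:
    """Multi-resolution RGB raster: ordered ``(mpp, HxWx3 uint8)`` levels.

    Levels are ordered finest to coarsest with strictly increasing mpp,
    and every level's dims equal the level-0 dims scaled by the mpp
    ratio (rounded up).
    """

    levels: list[tuple[float, np.ndarray]]
    slide_id: str
    patient_id: str

    def __post_init__(self) -> None:
        if not self.levels:
            raise InvalidSpecError("pyramid must contain at least one level")
        mpps = [m for m, _ in self.levels]
        if any(b <= a for a, b in zip(mpps, mpps[1:])):
            raise InvalidSpecError("level mpp values must be strictly increasing")
        base_mpp, base = self.levels[0]
        for mpp, raster in self.levels:
            if raster.size == 0:
                raise InvalidSpecError("empty raster in pyramid")
            expect = level_dims(base.shape[:2], base_mpp, mpp)
            if raster.shape[:2] != expect:
                raise InvalidSpecError(
                    f"level at {mpp} mpp has dims {raster.shape[:2]}, expected {expect}"
                )

    @property
    def base_mpp(self) -> float:
        return self.levels[0][0]

    def mpps(self) -> list[float]:
        return [m for m, _ in self.levels]

    def level(self, mpp: float) -> np.ndarray:
        """Exact-level lookup; KeyError if the pyramid has no such level."""
        for m, raster in self.levels:
            if np.isclose(m, mpp):
                return raster
        raise KeyError(f"no pyramid level at {mpp} mpp")

    def closest_finer(self, mpp: float) -> tuple[float, np.ndarray]:
        """The level with the largest mpp that does not exceed ``mpp``."""
        best = None
        for m, raster in self.levels:
            if m <= mpp * (1 + 1e-9):
                best = (m, raster)
        if best is None:
            raise InvalidSpecError(f"no pyramid level at or finer than {mpp} mpp")
        return best

    def raster_at(self, mpp: float) -> np.ndarray:
        """Raster at ``mpp``, derived by Lanczos downsampling if absent."""
        try:
            return self.level(mpp)
        except KeyError:
            from .synthetic_slides import resample_lanczos  # local import, no cycle at call time

            src_mpp, src = self.closest_finer(mpp)
            dims = level_dims(self.levels[0][1].shape[:2], self.base_mpp, mpp)
            return resample_lanczos(src, dims)


@dataclass
class TissueMask:
    """Binary tissue raster at mask resolution with provenance tag."""

    raster: np.ndarray
    mpp: float = MASK_MPP
    method: str = "threshold"
    slide_id: str = ""

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster)
        if self.raster.dtype != bool:
            uniq = np.unique(self.raster)
            if not np.all(np.isin(uniq, (0, 1))):
                raise InvalidSpecError("mask raster must be strictly binary")
            self.raster = self.raster.astype(bool)
        if self.method not in MASK_METHODS:
            raise InvalidSpecError(f"unknown mask method {self.method!r}")

    @property
    def n_tissue(self) -> int:
        return int(self.raster.sum())


@dataclass
class GroundTruth:
    """Planted truth for one synthetic slide, rasterized at 8.0 µm/px.

    ``lesion_mask`` is pixel-wise contained in ``tissue_mask`` and
    ``isup_label`` is 0 exactly when the lesion mask is empty.
    """

    tissue_mask: np.ndarray
    lesion_mask: np.ndarray
    isup_label: int

    def __post_init__(self) -> None:
        self.tissue_mask = np.asarray(self.tissue_mask, dtype=bool)
        self.lesion_mask = np.asarray(self.lesion_mask, dtype=bool)
        if self.tissue_mask.shape != self.lesion_mask.shape:
            raise InvalidSpecError("tissue and lesion masks must share dims")
        if np.any(self.lesion_mask & ~self.tissue_mask):
            raise InvalidSpecError("lesion mask must be a subset of the tissue mask")
        has_lesion = bool(self.lesion_mask.any())
        if has_lesion != (self.isup_label > 0):
            raise InvalidSpecError("isup_label must be 0 iff the lesion mask is empty")
        if not 0 <= self.isup_label <= 5:
            raise InvalidSpecError("isup_label must be in 0..5")

    def as_mask(self, slide_id: str = "") -> TissueMask:
        return TissueMask(self.tissue_mask, MASK_MPP, "truth", slide_id)
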