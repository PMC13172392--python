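"""Classical tissue detection: Otsu's global threshold plus morphology.

The pipeline runs entirely at the 8.0 µm/px mask resolution:

    extract 8 µm/px raster -> channel transform -> Gaussian blur ->
    Otsu threshold -> binary mask -> closing -> opening ->
    remove small objects -> fill small holes

Two channel transforms are provided.  Inverted luminance (default)
targets the usual case of tissue darker than background; saturation
separates pale eosin-only tissue that barely differs in luminance.  The
``min_channel_level`` floor models the fixed contrast assumption baked
into a single uniform parameter set: foreground must clear a minimum
level in the transformed channel, so washed-out tissue below the floor
yields an empty mask — a detection failure to be tallied, not an
exception.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage import morphology

from .core import (
    MASK_MPP,
    DegenerateHistogramError,
    InvalidSpecError,
    SlidePyramid,
    TissueMask,
    luminance,
)


@dataclass(frozen=True)
class ThresholdParams:
    channel_mode: str = "luminance_inverted"  # or "saturation"
    blur_radius_px: int = 1
    close_radius_px: int = 1
    open_radius_px: int = 1
    min_object_area_px: int = 32
    max_hole_area_px: int = 64
    min_channel_level: int = 0
    preset_name: str = "custom"

    def validate(self) -> None:
        if self.channel_mode not in ("luminance_inverted", "saturation"):
            raise InvalidSpecError(f"unknown channel mode {self.channel_mode!r}")
        for name in ("blur_radius_px", "close_radius_px", "open_radius_px",
                     "min_object_area_px", "max_hole_area_px", "min_channel_level"):
            if getattr(self, name) < 0:
                raise InvalidSpecError(f"{name} must be non-negative")


#: Named presets.  "uniform" is the single parameter set applied to every
#: slide in the paired comparison; its contrast floor is tuned for
#: normally stained tissue and is the designed point of failure on pale
#: slides.  "saturation" is the alternative transform for pale tissue.
PRESETS: dict[str, ThresholdParams] = {
    "uniform": ThresholdParams(preset_name="uniform", min_channel_level=20),
    "uniform_no_floor": ThresholdParams(preset_name="uniform_no_floor"),
    "saturation": ThresholdParams(channel_mode="saturation",
                                  preset_name="saturation", min_channel_level=0),
}


def get_preset(name: str) -> ThresholdParams:
    try:
        return PRESETS[name]
    except KeyError:
        raise InvalidSpecError(f"unknown threshold preset {name!r}") from None


# ---------------------------------------------------------------------------
# Otsu's method


def otsu_threshold(gray_histogram: np.ndarray) -> int:
    """Otsu's optimal cut over a 256-bin histogram.

    Returns the level t maximizing between-class variance of the split
    {bins <= t} vs {bins > t}, t in 0..254; ties break to the smallest t.
    A histogram whose mass sits in a single bin admits no split and
    raises :class:`DegenerateHistogramError`.
    """
    hist = np.asarray(gray_histogram, dtype=np.float64)
    if hist.ndim != 1 or hist.size != 256:
        raise InvalidSpecError("histogram must have 256 bins")
    if hist.sum() < 1:
        raise InvalidSpecError("histogram must contain at least one count")
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError("all histogram mass in a single bin")

    levels = np.arange(256, dtype=np.float64)
    total = hist.sum()
    w0 = np.cumsum(hist)[:-1]                      # mass of class <= t, t=0..254
    w1 = total - w0
    csum = np.cumsum(hist * levels)[:-1]
    mu0 = np.divide(csum, w0, out=np.zeros_like(csum), where=w0 > 0)
    mu1 = np.divide(csum[-1] + hist[255] * 255 - csum, w1,
                    out=np.zeros_like(csum), where=w1 > 0)
    between = w0 * w1 * (mu0 - mu1) ** 2
    between[(w0 == 0) | (w1 == 0)] = -np.inf
    return int(np.argmax(between))                 # argmax takes the first (smallest) tie


# ---------------------------------------------------------------------------
# Channel transforms


def channel_transform(rgb: np.ndarray, mode: str) -> np.ndarray:
    """Map an RGB raster to the scalar channel being thresholded (0..255)."""
    if mode == "luminance_inverted":
        return 255.0 - luminance(rgb)
    if mode == "saturation":
        rgbf = np.asarray(rgb, dtype=np.float64)
        mx = rgbf.max(axis=-1)
        mn = rgbf.min(axis=-1)
        sat = np.divide(mx - mn, mx, out=np.zeros_like(mx), where=mx > 0)
        return sat * 255.0
    raise InvalidSpecError(f"unknown channel mode {mode!r}")


# ---------------------------------------------------------------------------
# Full segmentation pipeline


def _cleanup(mask: np.ndarray, params: ThresholdParams) -> np.ndarray:
    out = mask
    if params.close_radius_px > 0:
        out = morphology.closing(out, morphology.disk(params.close_radius_px))
    if params.open_radius_px > 0:
        out = morphology.opening(out, morphology.disk(params.open_radius_px))
    if params.min_object_area_px > 1:
        # remove objects strictly smaller than the configured minimum
        out = morphology.remove_small_objects(out, max_size=params.min_object_area_px - 1)
    if params.max_hole_area_px > 1:
        out = morphology.remove_small_holes(out, max_size=params.max_hole_area_px - 1)
    return out


def cleanup_chain(mask: np.ndarray, params: ThresholdParams) -> np.ndarray:
    """Morphological cleanup: close -> open -> area filter -> hole fill."""
    return _cleanup(np.asarray(mask, dtype=bool), params)


def segment(slide: SlidePyramid, params: ThresholdParams) -> TissueMask:
    """Threshold-based tissue mask at 8.0 µm/px.

    A degenerate histogram (e.g. a constant raster) yields an empty mask
    rather than an exception; the caller tallies it as a detection
    failure via :func:`is_detection_failure`.
    """
    params.validate()
    raster = slide.raster_at(MASK_MPP)
    chan = channel_transform(raster, params.channel_mode)
    if params.blur_radius_px > 0:
        chan = ndimage.gaussian_filter(chan, params.blur_radius_px)
    chan = np.clip(chan, 0, 255)
    hist = np.bincount(np.round(chan).astype(np.int64).ravel(), minlength=256)[:256]
    try:
        level = otsu_threshold(hist)
    except DegenerateHistogramError:
        return TissueMask(np.zeros(chan.shape, dtype=bool), MASK_MPP,
                          "threshold", slide.slide_id)
    level = max(level, params.min_channel_level)
    mask = chan > level
    mask = _cleanup(mask, params)
    return TissueMask(mask, MASK_MPP, "threshold", slide.slide_id)


def is_detection_failure(mask: TissueMask) -> bool:
    """True iff the mask contains zero tissue pixels."""
    return mask.n_tissue == 0
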