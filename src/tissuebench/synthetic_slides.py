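"""Synthetic pyramidal slides with exact planted ground truth.

Emulates H&E core-needle biopsy slides at desk scale: a bright, mildly
textured background carrying a few elongated tissue fragments (unions of
randomly deformed ellipses), optionally a planted graded lesion region
inside one fragment, and non-tissue artifacts (pen marks, debris).  Two
color regimes are modelled:

``normal``
    tissue clearly darker than background, as in well-stained H&E;
``pale``
    tissue whose mean luminance sits within ``PALE_DELTA`` of the
    background — the washed-out, eosin-only appearance on which fixed
    thresholding parameters fail;
``mixed``
    one normal fragment plus pale fragments, the lesion planted in a
    pale fragment, so that a luminance thresholder finds *some* tissue
    (no outright detection failure) while missing the lesion-bearing
    fragment entirely.

Ground truth is rasterized at 8.0 µm/px by area-majority of the analytic
fragment shapes.  Everything is driven by a single per-slide random
stream derived from ``(seed, slide_id)`` so cohorts are reproducible
slide by slide.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage.measure import block_reduce

from .core import (
    MASK_MPP,
    GroundTruth,
    InvalidSpecError,
    SlidePyramid,
    level_dims,
    luminance,
)

# ---------------------------------------------------------------------------
# Appearance constants (RGB in 0..255)

BACKGROUND_RGB = np.array([246.0, 246.0, 246.0])
BACKGROUND_NOISE_SD = 2.0

NORMAL_TISSUE_RGB = np.array([205.0, 140.0, 185.0])   # eosin/hematoxylin mix
NORMAL_TISSUE_NOISE_SD = 5.0
NORMAL_LESION_SHIFT = np.array([-30.0, -35.0, -15.0])  # denser, more basophilic

PALE_TISSUE_RGB = np.array([242.0, 237.0, 241.0])      # washed-out eosin remnant
PALE_TISSUE_NOISE_SD = 2.5
PALE_LESION_SHIFT = np.array([-2.0, -2.0, -1.0])       # essentially invisible

#: Guaranteed upper bound on |mean tissue luma - mean background luma|
#: for pale-profile fragments, in luminance units.
PALE_DELTA = 8.0

PEN_RGB = np.array([40.0, 70.0, 200.0])
PEN_WIDTH_UM = 60.0
DEBRIS_RGB = np.array([95.0, 75.0, 60.0])
DEBRIS_RADIUS_UM = (4.0, 12.0)

DEFAULT_LEVEL_MPPS = (1.0, 2.0, 4.0, 8.0)

#: Expected tissue area fraction band for default cohort slides.
TISSUE_FRACTION_BAND = (0.03, 0.45)


@dataclass(frozen=True)
class LesionSpec:
    """A planted graded lesion: ISUP grade and its share of tissue area."""

    isup_grade: int
    area_fraction: float = 0.25


@dataclass(frozen=True)
class SyntheticSlideSpec:
    """Full recipe for one synthetic slide."""

    width_um: float = 1536.0
    height_um: float = 1536.0
    base_mpp: float = 1.0
    n_fragments: int = 3
    fragment_scale_um: float = 600.0
    color_profile: str = "normal"        # normal | pale | mixed
    artifacts: frozenset = frozenset()   # subset of {"pen_mark", "debris"}
    lesion: LesionSpec | None = None
    seed: int = 0
    slide_id: str = "S0"
    patient_id: str = "P0"

    def validate(self) -> None:
        if self.width_um <= 0 or self.height_um <= 0:
            raise InvalidSpecError("slide must have positive physical extent")
        if self.base_mpp <= 0:
            raise InvalidSpecError("base_mpp must be positive")
        if self.n_fragments < 0:
            raise InvalidSpecError("n_fragments must be non-negative")
        if self.color_profile not in ("normal", "pale", "mixed"):
            raise InvalidSpecError(f"unknown color profile {self.color_profile!r}")
        if not self.artifacts <= {"pen_mark", "debris", "none"}:
            raise InvalidSpecError(f"unknown artifacts {self.artifacts!r}")
        if self.lesion is not None:
            if not 1 <= self.lesion.isup_grade <= 5:
                raise InvalidSpecError("lesion isup_grade must be in 1..5")
            if not 0 < self.lesion.area_fraction <= 1:
                raise InvalidSpecError("lesion area_fraction must be in (0, 1]")


# ---------------------------------------------------------------------------
# Resampling and pyramid assembly


def resample_lanczos(raster: np.ndarray, dims: tuple[int, int]) -> np.ndarray:
    """Lanczos-resample an HxW or HxWx3 uint8 raster to (h, w) dims."""
    img = Image.fromarray(np.ascontiguousarray(raster))
    out = img.resize((dims[1], dims[0]), Image.Resampling.LANCZOS)
    return np.asarray(out)


def build_pyramid(
    base_raster: np.ndarray,
    base_mpp: float,
    target_mpps: Sequence[float],
    slide_id: str = "S0",
    patient_id: str = "P0",
) -> SlidePyramid:
    """Assemble a pyramid by successive Lanczos downsampling.

    Each requested level is produced from the closest finer level already
    available (the base or a previously built level), never by
    upsampling.  ``target_mpps`` must be sorted ascending and start at or
    above ``base_mpp``.
    """
    mpps = list(target_mpps)
    if any(b <= a for a, b in zip(mpps, mpps[1:])):
        raise InvalidSpecError("target_mpps must be strictly increasing")
    if mpps and mpps[0] < base_mpp * (1 - 1e-9):
        raise InvalidSpecError("cannot build a level finer than the base raster")
    levels: list[tuple[float, np.ndarray]] = []
    base_dims = base_raster.shape[:2]
    for mpp in mpps:
        if np.isclose(mpp, base_mpp):
            levels.append((base_mpp, base_raster.copy()))
            continue
        src_mpp, src = (base_mpp, base_raster)
        for m, r in levels:
            if m <= mpp * (1 + 1e-9) and m > src_mpp:
                src_mpp, src = m, r
        dims = level_dims(base_dims, base_mpp, mpp)
        levels.append((mpp, resample_lanczos(src, dims)))
    return SlidePyramid(levels, slide_id, patient_id)


# ---------------------------------------------------------------------------
# Fragment geometry


def _slide_rng(seed: int, slide_id: str) -> np.random.Generator:
    # stable across processes: CRC32 of the slide id folded into the seed
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(slide_id.encode())])


def _fragment_params(rng: np.random.Generator, spec: SyntheticSlideSpec) -> dict:
    scale = spec.fragment_scale_um
    a = scale * rng.uniform(0.50, 0.70)
    b = a * rng.uniform(0.30, 0.50)
    cx = rng.uniform(0.25, 0.75) * spec.width_um
    cy = rng.uniform(0.25, 0.75) * spec.height_um
    theta = rng.uniform(0.0, np.pi)
    ks = np.arange(2, 6)
    cos_amp = rng.normal(0.0, 0.04, ks.size)
    sin_amp = rng.normal(0.0, 0.04, ks.size)
    return dict(a=a, b=b, cx=cx, cy=cy, theta=theta, ks=ks,
                cos_amp=cos_amp, sin_amp=sin_amp)


def _fragment_rho(frag: dict, xx: np.ndarray, yy: np.ndarray) -> np.ndarray:
    """Normalized radial coordinate of each pixel w.r.t. a fragment.

    Inside the (deformed) fragment boundary iff rho <= 1 + delta(phi).
    Returns rho / (1 + delta), so the indicator is simply ``<= 1``.
    """
    ct, st = np.cos(frag["theta"]), np.sin(frag["theta"])
    dx = xx - frag["cx"]
    dy = yy - frag["cy"]
    u = (ct * dx + st * dy) / frag["a"]
    v = (-st * dx + ct * dy) / frag["b"]
    rho = np.hypot(u, v)
    phi = np.arctan2(v, u)
    delta = np.zeros_like(phi)
    for k, c, s in zip(frag["ks"], frag["cos_amp"], frag["sin_amp"]):
        delta += c * np.cos(k * phi) + s * np.sin(k * phi)
    delta = np.clip(delta, -0.35, 0.35)
    return rho / (1.0 + delta)


def _pen_stroke_mask(rng: np.random.Generator, shape: tuple[int, int],
                     mpp: float, width_um: float) -> np.ndarray:
    """Thick polyline stroke rendered as a boolean raster."""
    h, w = shape
    npts = rng.integers(3, 5)
    pts = np.column_stack([rng.uniform(0.1 * w, 0.9 * w, npts),
                           rng.uniform(0.1 * h, 0.9 * h, npts)])
    canvas = np.zeros(shape, dtype=bool)
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        n = int(max(abs(x1 - x0), abs(y1 - y0))) + 1
        xs = np.linspace(x0, x1, n).astype(int).clip(0, w - 1)
        ys = np.linspace(y0, y1, n).astype(int).clip(0, h - 1)
        canvas[ys, xs] = True
    r = max(1, int(round(width_um / (2 * mpp))))
    return ndimage.binary_dilation(canvas, ndimage.generate_binary_structure(2, 2), iterations=r)


# ---------------------------------------------------------------------------
# Slide generation


def generate_slide(spec: SyntheticSlideSpec) -> tuple[SlidePyramid, GroundTruth]:
    """Render one slide and its exact ground truth.

    Deterministic for a fixed ``(seed, slide_id)``.  Artifacts are drawn
    only outside tissue and labelled background in the truth, so any
    segmenter that picks them up pays a measurable precision penalty.
    """
    spec.validate()
    rng = _slide_rng(spec.seed, spec.slide_id)

    h = int(round(spec.height_um / spec.base_mpp))
    w = int(round(spec.width_um / spec.base_mpp))
    if h == 0 or w == 0:
        raise InvalidSpecError("slide raster has zero area")

    yy, xx = np.mgrid[0:h, 0:w]
    xx_um = (xx + 0.5) * spec.base_mpp
    yy_um = (yy + 0.5) * spec.base_mpp

    fragments = [_fragment_params(rng, spec) for _ in range(spec.n_fragments)]
    rho_maps = [_fragment_rho(f, xx_um, yy_um) for f in fragments]
    frag_masks = [r <= 1.0 for r in rho_maps]
    tissue = np.zeros((h, w), dtype=bool)
    for m in frag_masks:
        tissue |= m

    # per-fragment color profile
    if spec.color_profile == "mixed" and spec.n_fragments >= 1:
        profiles = ["pale"] * spec.n_fragments
        profiles[0] = "normal"
    else:
        profiles = [spec.color_profile] * spec.n_fragments

    # lesion: planted inside one fragment as an inner level set of rho
    lesion = np.zeros((h, w), dtype=bool)
    lesion_frag = -1
    if spec.lesion is not None and spec.n_fragments > 0:
        candidates = [i for i, p in enumerate(profiles) if p == "pale"] \
            if spec.color_profile == "mixed" else list(range(spec.n_fragments))
        areas = [int(frag_masks[i].sum()) for i in candidates]
        if max(areas, default=0) > 0:
            lesion_frag = candidates[int(np.argmax(areas))]
            target = spec.lesion.area_fraction * tissue.sum()
            inside = rho_maps[lesion_frag][frag_masks[lesion_frag]]
            n_take = int(min(target, 0.95 * inside.size))
            if n_take >= 1:
                q = np.partition(inside, n_take - 1)[n_take - 1]
                lesion = frag_masks[lesion_frag] & (rho_maps[lesion_frag] <= q)

    # ---- render level 0 ----
    img = BACKGROUND_RGB[None, None, :] + rng.normal(0.0, BACKGROUND_NOISE_SD, (h, w, 3))
    for i, (fmask, prof) in enumerate(zip(frag_masks, profiles)):
        base_rgb = NORMAL_TISSUE_RGB if prof == "normal" else PALE_TISSUE_RGB
        noise_sd = NORMAL_TISSUE_NOISE_SD if prof == "normal" else PALE_TISSUE_NOISE_SD
        npix = int(fmask.sum())
        if npix == 0:
            continue
        vals = base_rgb[None, :] + rng.normal(0.0, noise_sd, (npix, 3))
        img[fmask] = vals
        if i == lesion_frag and lesion.any():
            shift = NORMAL_LESION_SHIFT if prof == "normal" else PALE_LESION_SHIFT
            img[lesion & fmask] += shift[None, :]

    artifacts = set(spec.artifacts) - {"none"}
    if "pen_mark" in artifacts:
        pen = _pen_stroke_mask(rng, (h, w), spec.base_mpp, PEN_WIDTH_UM) & ~tissue
        img[pen] = PEN_RGB[None, :] + rng.normal(0.0, 3.0, (int(pen.sum()), 3))
    if "debris" in artifacts:
        n_specks = int(rng.integers(15, 30))
        for _ in range(n_specks):
            r_um = rng.uniform(*DEBRIS_RADIUS_UM)
            cx = rng.uniform(0, spec.width_um)
            cy = rng.uniform(0, spec.height_um)
            speck = (xx_um - cx) ** 2 + (yy_um - cy) ** 2 <= r_um ** 2
            speck &= ~tissue
            if speck.any():
                img[speck] = DEBRIS_RGB[None, :] + rng.normal(0.0, 4.0, (int(speck.sum()), 3))

    base = np.clip(img, 0, 255).astype(np.uint8)
    pyramid = build_pyramid(base, spec.base_mpp, DEFAULT_LEVEL_MPPS,
                            spec.slide_id, spec.patient_id)

    # ---- ground truth at mask resolution by area-majority ----
    block = int(round(MASK_MPP / spec.base_mpp))
    tissue_mask = _majority_downsample(tissue, block)
    lesion_mask = _majority_downsample(lesion, block) & tissue_mask
    isup = spec.lesion.isup_grade if (spec.lesion is not None and lesion_mask.any()) else 0
    truth = GroundTruth(tissue_mask, lesion_mask, isup)
    return pyramid, truth


def _majority_downsample(mask: np.ndarray, block: int) -> np.ndarray:
    h, w = mask.shape
    ph = (-h) % block
    pw = (-w) % block
    if ph or pw:
        mask = np.pad(mask, ((0, ph), (0, pw)))
    frac = block_reduce(mask.astype(np.float64), (block, block), np.mean)
    return frac >= 0.5


# ---------------------------------------------------------------------------
# Patient-level splitting


def split_by_patient(cases: Sequence, fractions: Sequence[float], seed: int) -> list[list]:
    """Partition cases so that each patient's cases land in one cell.

    ``cases`` may be objects exposing ``patient_id`` or plain strings
    (treated as patient ids themselves).  Cell sizes follow the target
    fractions in *patient* counts via largest-remainder rounding, exact
    when the patient count divides evenly.
    """
    if len(cases) == 0:
        raise InvalidSpecError("cannot split an empty case list")
    fr = np.asarray(fractions, dtype=float)
    if fr.ndim != 1 or fr.size == 0 or np.any(fr < 0) or not np.isclose(fr.sum(), 1.0):
        raise InvalidSpecError("fractions must be non-negative and sum to 1")

    def pid(c):
        return getattr(c, "patient_id", c)

    patients = sorted({pid(c) for c in cases})
    order = np.random.default_rng(seed).permutation(len(patients))
    patients = [patients[i] for i in order]

    n = len(patients)
    raw = fr * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    if rem:
        frac_order = np.argsort(-(raw - counts), kind="stable")
        for i in frac_order[:rem]:
            counts[i] += 1

    cells: list[list] = []
    start = 0
    for c in counts:
        cell_patients = set(patients[start:start + c])
        cells.append([case for case in cases if pid(case) in cell_patients])
        start += c
    return cells


# ---------------------------------------------------------------------------
# Cohort assembly


def cohort_specs(
    n_slides: int,
    seed: int,
    pale_fraction: float = 0.20,
    artifact_fraction: float = 0.15,
    empty_fraction: float = 0.07,
    lesion_fraction: float = 0.60,
    mixed_fraction: float = 0.0,
    prefix: str = "S",
) -> list[SyntheticSlideSpec]:
    """Deterministic recipe list for a study cohort.

    The composition mirrors the data regimes of interest: mostly normal
    slides, a pale minority (the thresholding failure mode), a sprinkle
    of artifact-bearing slides, a few empty slides, and graded lesions on
    a majority of tissue-bearing slides.  One patient per slide.
    """
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0xC04])
    n_pale = int(round(pale_fraction * n_slides))
    n_mixed = int(round(mixed_fraction * n_slides))
    n_empty = int(round(empty_fraction * n_slides))
    n_artifact = int(round(artifact_fraction * n_slides))

    roles = (["pale"] * n_pale + ["mixed"] * n_mixed + ["empty"] * n_empty)
    roles += ["normal"] * (n_slides - len(roles))
    rng.shuffle(roles)
    artifact_ids = set(rng.choice(
        [i for i, r in enumerate(roles) if r in ("normal", "pale")],
        size=min(n_artifact, sum(r in ("normal", "pale") for r in roles)),
        replace=False,
    ).tolist()) if n_artifact else set()

    specs = []
    grade_cycle = 0
    for i, role in enumerate(roles):
        sid = f"{prefix}{i:03d}"
        lesion = None
        if role != "empty" and rng.random() < lesion_fraction:
            grade_cycle += 1
            lesion = LesionSpec(isup_grade=1 + (grade_cycle - 1) % 5, area_fraction=0.25)
        arts = frozenset()
        if i in artifact_ids:
            arts = frozenset({"pen_mark"} if rng.random() < 0.5 else {"debris"})
        specs.append(SyntheticSlideSpec(
            n_fragments=0 if role == "empty" else int(rng.integers(2, 5)),
            color_profile="normal" if role in ("normal", "empty") else role,
            artifacts=arts,
            lesion=lesion,
            seed=seed,
            slide_id=sid,
            patient_id=f"{prefix}pat{i:03d}",
        ))
    return specs


def cohort_manifest(specs: Iterable[SyntheticSlideSpec]) -> pd.DataFrame:
    """Tidy manifest of a cohort (one row per slide)."""
    rows = []
    for s in specs:
        rows.append(dict(
            slide_id=s.slide_id,
            patient_id=s.patient_id,
            isup_label=0 if s.lesion is None else s.lesion.isup_grade,
            color_profile=s.color_profile,
            n_fragments=s.n_fragments,
            pen_mark="pen_mark" in s.artifacts,
            debris="debris" in s.artifacts,
            seed=s.seed,
        ))
    return pd.DataFrame(rows)
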