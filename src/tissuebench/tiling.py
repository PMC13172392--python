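"""Grading-model tile extraction and the 10%-tissue filter.

Grading tiles live at a finer resolution (1.0 µm/px, 256-px tiles) than
the segmentation masks (8.0 µm/px); the integer scale factor between the
two lets the tissue fraction of a tile be read directly off the aligned
mask window.  The tile grid is anchored at the slide origin and mirrors
only past the far edges, so tile coordinates stay aligned to the mask
grid.  "128 pixel overlap" between neighbouring 256-px inference tiles
corresponds to a 64-px discarded margin per edge under the single rule
stride = tile - 2 * overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import InvalidSpecError, SlidePyramid, TissueMask
from .synthetic_slides import resample_lanczos


@dataclass(frozen=True)
class TilingConfig:
    mask_mpp: float = 8.0
    tile_mpp: float = 1.0
    tile_size_px: int = 256
    train_overlap_px: int = 0
    infer_overlap_px: int = 64
    min_tissue_fraction: float = 0.10

    @property
    def scale_factor(self) -> int:
        ratio = self.mask_mpp / self.tile_mpp
        if not np.isclose(ratio, round(ratio)) or ratio < 1:
            raise InvalidSpecError("mask_mpp / tile_mpp must be a positive integer")
        return int(round(ratio))

    def validate(self) -> None:
        s = self.scale_factor
        if self.tile_size_px % s:
            raise InvalidSpecError("tile_size_px must be divisible by the scale factor")
        if not 0.0 <= self.min_tissue_fraction <= 1.0:
            raise InvalidSpecError("min_tissue_fraction must be in [0, 1]")
        for ov in (self.train_overlap_px, self.infer_overlap_px):
            if ov < 0:
                raise InvalidSpecError("overlaps must be non-negative")

    def stride(self, mode: str) -> int:
        if mode not in ("train", "infer"):
            raise InvalidSpecError(f"unknown tiling mode {mode!r}")
        overlap = self.train_overlap_px if mode == "train" else self.infer_overlap_px
        stride = self.tile_size_px - 2 * overlap
        if stride <= 0:
            raise InvalidSpecError("overlap must be < tile_size / 2 (stride would be <= 0)")
        return stride


@dataclass(frozen=True)
class TileRecord:
    x: int
    y: int
    tissue_fraction: float
    raster: np.ndarray | None = None


@dataclass
class TileSet:
    """Tiles of one slide surviving the tissue-fraction filter."""

    slide_id: str
    records: list[TileRecord]
    config: TilingConfig

    def __len__(self) -> int:
        return len(self.records)

    def coords(self) -> list[tuple[int, int]]:
        return [(r.x, r.y) for r in self.records]


# ---------------------------------------------------------------------------


def grid_tiles(
    slide_dims: tuple[int, int], config: TilingConfig, mode: str = "train"
) -> list[tuple[int, int]]:
    """Row-major (x, y) tile origins covering the mirror-padded extent.

    ``slide_dims`` are (height, width) at ``tile_mpp``.  Train mode uses
    stride = tile size; infer mode stride = tile - 2 * overlap.
    """
    config.validate()
    h, w = slide_dims
    if h <= 0 or w <= 0:
        raise InvalidSpecError("slide dims must be positive")
    t = config.tile_size_px
    s = config.stride(mode)
    if s % config.scale_factor:
        raise InvalidSpecError("stride must be divisible by the mask scale factor")

    def n_tiles(dim: int) -> int:
        return 1 if dim <= t else int(np.ceil((dim - t) / s)) + 1

    return [(c * s, r * s) for r in range(n_tiles(h)) for c in range(n_tiles(w))]


def padded_dims(slide_dims: tuple[int, int], config: TilingConfig, mode: str) -> tuple[int, int]:
    """Extent covered by the tile grid (>= slide dims)."""
    coords = grid_tiles(slide_dims, config, mode)
    t = config.tile_size_px
    return (max(y for _, y in coords) + t, max(x for x, _ in coords) + t)


def tissue_fraction(
    mask: TissueMask | np.ndarray, tile_coord: tuple[int, int], config: TilingConfig
) -> float:
    """Tissue share of the mask window under one tile footprint.

    The tile footprint at tile resolution maps to a (tile/scale)^2
    window of the mask; footprints extending past the mask (mirrored
    grid margin) are clipped and normalized by the clipped area.
    """
    raster = mask.raster if isinstance(mask, TissueMask) else np.asarray(mask, bool)
    s = config.scale_factor
    x, y = tile_coord
    if x % s or y % s:
        raise InvalidSpecError("tile coords must be divisible by the scale factor")
    side = config.tile_size_px // s
    y0, x0 = y // s, x // s
    window = raster[y0:y0 + side, x0:x0 + side]
    if window.size == 0:
        return 0.0
    return float(window.sum() / window.size)


def filter_tiles(
    coords: Sequence[tuple[int, int]], mask: TissueMask | np.ndarray, config: TilingConfig
) -> TileSet:
    """Keep tiles with tissue fraction >= the configured minimum (inclusive)."""
    config.validate()
    slide_id = mask.slide_id if isinstance(mask, TissueMask) else ""
    records = []
    for x, y in coords:
        frac = tissue_fraction(mask, (x, y), config)
        if frac >= config.min_tissue_fraction:
            records.append(TileRecord(x, y, frac))
    return TileSet(slide_id, records, config)


def extract_tile(
    pyramid: SlidePyramid, coord: tuple[int, int], config: TilingConfig
) -> np.ndarray:
    """RGB tile at ``tile_mpp`` from the closest finer pyramid level.

    The source level is the one with the largest mpp not exceeding the
    target; a crop at an exactly matching level is returned bit-exact,
    otherwise the crop is Lanczos-resampled to the tile size.  Regions
    past the slide edge are mirror-extended.
    """
    src_mpp, src = pyramid.closest_finer(config.tile_mpp)
    factor = config.tile_mpp / src_mpp
    x, y = coord
    t = config.tile_size_px
    sx, sy = int(round(x * factor)), int(round(y * factor))
    side = int(round(t * factor))
    crop = _crop_mirrored(src, sy, sx, side, side)
    if np.isclose(src_mpp, config.tile_mpp):
        return crop
    return resample_lanczos(crop, (t, t))


def _crop_mirrored(raster: np.ndarray, y0: int, x0: int, h: int, w: int) -> np.ndarray:
    H, W = raster.shape[:2]
    pad_b = max(0, y0 + h - H)
    pad_r = max(0, x0 + w - W)
    if pad_b or pad_r:
        pad = [(0, pad_b), (0, pad_r)] + [(0, 0)] * (raster.ndim - 2)
        raster = np.pad(raster, pad, mode="symmetric")
    return raster[y0:y0 + h, x0:x0 + w]


def tile_slide(
    pyramid: SlidePyramid,
    mask: TissueMask,
    config: TilingConfig,
    mode: str = "train",
    with_rasters: bool = False,
) -> TileSet:
    """Grid, filter, and optionally extract rasters for one slide."""
    level0 = pyramid.levels[0][1]
    dims_tile = (
        int(np.ceil(level0.shape[0] * pyramid.base_mpp / config.tile_mpp)),
        int(np.ceil(level0.shape[1] * pyramid.base_mpp / config.tile_mpp)),
    )
    coords = grid_tiles(dims_tile, config, mode)
    tiles = filter_tiles(coords, mask, config)
    if with_rasters:
        tiles.records = [
            TileRecord(r.x, r.y, r.tissue_fraction,
                       extract_tile(pyramid, (r.x, r.y), config))
            for r in tiles.records
        ]
    return tiles
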