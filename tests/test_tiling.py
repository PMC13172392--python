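"""Tile-grid arithmetic, the 10%-tissue rule, and pyramid-level tile
extraction."""

import numpy as np
import pytest

from tissuebench.core import InvalidSpecError, SlidePyramid, TissueMask
from tissuebench.tiling import (
    TilingConfig,
    extract_tile,
    filter_tiles,
    grid_tiles,
    padded_dims,
    tissue_fraction,
)


class TestGridTiles:
    def test_exact_single_tile(self):
        cfg = TilingConfig()
        assert grid_tiles((256, 256), cfg, "train") == [(0, 0)]

    def test_ceiling_arithmetic_600x700(self):
        cfg = TilingConfig()
        coords = grid_tiles((600, 700), cfg, "train")
        assert len(coords) == 9
        assert padded_dims((600, 700), cfg, "train") == (768, 768)

    def test_infer_overlap_half_tile_rejected(self):
        cfg = TilingConfig(infer_overlap_px=128)
        with pytest.raises(InvalidSpecError):
            grid_tiles((512, 512), cfg, "infer")

    def test_infer_stride_arithmetic(self):
        cfg = TilingConfig(infer_overlap_px=64)
        coords = grid_tiles((512, 512), cfg, "infer")
        assert len(coords) == 9  # stride 128: origins 0,128,256 each axis
        assert coords[0] == (0, 0) and coords[-1] == (256, 256)

    @pytest.mark.parametrize("mode", ["train", "infer"])
    @pytest.mark.parametrize("dims", [(300, 300), (256, 520), (1000, 700)])
    def test_grid_reconstructs_padded_extent(self, dims, mode):
        cfg = TilingConfig()
        coords = grid_tiles(dims, cfg, mode)
        s = cfg.stride(mode)
        xs = sorted({x for x, _ in coords})
        ys = sorted({y for _, y in coords})
        assert all(b - a == s for a, b in zip(xs, xs[1:]))
        assert all(b - a == s for a, b in zip(ys, ys[1:]))
        ph, pw = padded_dims(dims, cfg, mode)
        assert ph >= dims[0] and pw >= dims[1]
        assert ph - dims[0] < cfg.tile_size_px and pw - dims[1] < cfg.tile_size_px
        # row-major ordering
        assert coords == sorted(coords, key=lambda c: (c[1], c[0]))


class TestTissueFraction:
    cfg = TilingConfig(tile_size_px=160)  # 20x20 mask window

    def test_empty_and_full(self):
        empty = np.zeros((40, 40), bool)
        full = np.ones((40, 40), bool)
        assert tissue_fraction(empty, (0, 0), self.cfg) == 0.0
        assert tissue_fraction(full, (0, 0), self.cfg) == 1.0

    def test_constructed_half_window(self):
        mask = np.zeros((20, 20), bool)
        mask.ravel()[:200] = True  # 200 of 400 pixels
        assert tissue_fraction(mask, (0, 0), self.cfg) == 0.5

    def test_clipped_footprint_normalizes_by_clipped_area(self):
        mask = np.ones((30, 20), bool)  # window at y=160 covers rows 20..29 only
        assert tissue_fraction(mask, (0, 160), self.cfg) == 1.0

    def test_misaligned_coord_rejected(self):
        with pytest.raises(InvalidSpecError):
            tissue_fraction(np.ones((20, 20), bool), (3, 0), self.cfg)


class TestFilterTiles:
    def test_boundary_inclusive_at_10_percent(self):
        cfg = TilingConfig(tile_size_px=160)
        mask = np.zeros((20, 60), bool)
        # windows: 20, 40, 200 tissue pixels of 400 -> 0.05, 0.10, 0.50
        mask[:1, 0:20] = True            # 20 px
        mask[:2, 20:40] = True           # 40 px
        mask[:10, 40:60] = True          # 200 px
        coords = [(0, 0), (160, 0), (320, 0)]
        kept = filter_tiles(coords, mask, cfg)
        assert kept.coords() == [(160, 0), (320, 0)]
        fr = [r.tissue_fraction for r in kept.records]
        assert fr == [pytest.approx(0.10), pytest.approx(0.50)]

    def test_empty_and_full_masks(self):
        cfg = TilingConfig()
        coords = grid_tiles((512, 512), cfg, "train")
        assert len(filter_tiles(coords, np.zeros((64, 64), bool), cfg)) == 0
        assert len(filter_tiles(coords, np.ones((64, 64), bool), cfg)) == len(coords)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(4)
        mask = rng.random((64, 64)) < 0.15
        coords = grid_tiles((512, 512), TilingConfig(), "train")
        kept_strict = {tuple(c) for c in filter_tiles(
            coords, mask, TilingConfig(min_tissue_fraction=0.10)).coords()}
        kept_loose = {tuple(c) for c in filter_tiles(
            coords, mask, TilingConfig(min_tissue_fraction=0.05)).coords()}
        assert kept_strict <= kept_loose

    def test_mask_scale_consistency_oracle(self):
        """Fraction on the 8 µm/px mask window equals the fraction on the
        nearest-neighbour upsampled full-resolution mask."""
        rng = np.random.default_rng(9)
        cfg = TilingConfig()
        s = cfg.scale_factor
        for _ in range(10):
            mask = rng.random((64, 64)) < rng.uniform(0.1, 0.6)
            up = np.repeat(np.repeat(mask, s, 0), s, 1)
            for coord in [(0, 0), (256, 0), (256, 256)]:
                x, y = coord
                win = up[y:y + cfg.tile_size_px, x:x + cfg.tile_size_px]
                assert tissue_fraction(mask, coord, cfg) == pytest.approx(win.mean())


class TestExtractTile:
    @staticmethod
    def two_level_pyramid():
        rng = np.random.default_rng(2)
        base = rng.integers(0, 256, (512, 512, 3), dtype=np.uint8)
        from tissuebench.synthetic_slides import build_pyramid
        return build_pyramid(base, 1.0, [1.0, 4.0], "xt", "xp"), base

    def test_matching_level_is_bit_exact_crop(self):
        pyr, base = self.two_level_pyramid()
        cfg = TilingConfig(tile_mpp=1.0)
        tile = extract_tile(pyr, (256, 0), cfg)
        np.testing.assert_array_equal(tile, base[0:256, 256:512])

    def test_source_is_closest_finer_level(self):
        # pyramid whose 4.0 level is deliberately wrong: if extraction at
        # 2.0 µm/px used it, values would be ~200, not ~100
        base = np.full((64, 64, 3), 100, np.uint8)
        wrong = np.full((16, 16, 3), 200, np.uint8)
        pyr = SlidePyramid([(1.0, base), (4.0, wrong)], "s", "p")
        cfg = TilingConfig(tile_mpp=2.0, tile_size_px=16, mask_mpp=8.0)
        tile = extract_tile(pyr, (0, 0), cfg)
        assert np.abs(tile.astype(int) - 100).max() <= 1

    def test_no_finer_level_rejected(self):
        pyr, _ = self.two_level_pyramid()
        with pytest.raises(InvalidSpecError):
            extract_tile(pyr, (0, 0), TilingConfig(tile_mpp=0.5, tile_size_px=256))

    def test_constant_region_resamples_to_constant(self):
        base = np.full((512, 512, 3), (50, 100, 150), np.uint8)
        from tissuebench.synthetic_slides import build_pyramid
        pyr = build_pyramid(base, 1.0, [1.0, 2.0], "c", "p")
        cfg = TilingConfig(tile_mpp=2.0, tile_size_px=128, mask_mpp=8.0)
        tile = extract_tile(pyr, (0, 0), cfg)
        assert (tile == np.array([50, 100, 150], np.uint8)).all()
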