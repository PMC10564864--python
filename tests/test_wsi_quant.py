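"""Quantification chain: masking, tiling, stain separation, aggregation."""

import numpy as np
import pytest

from glycoquant.stain import concentrations_from_rgb, rgb_from_concentrations
from glycoquant.synthetic_slides import SlideImage, SlideSynthesisConfig, synthesize_slide
from glycoquant.wsi_quant import (
    QuantParams,
    TileQuant,
    aggregate_slide,
    mask_tissue,
    quantify_slide,
    quantify_tile,
    spearman_validation,
    tile_slide,
)


def _white_slide(h=256, w=256):
    return SlideImage(np.full((h, w, 3), 255, dtype=np.uint8), 0.25, "white")


def _render_tile(h_conc, d_conc):
    conc = np.zeros(h_conc.shape + (3,))
    conc[..., 0] = h_conc
    conc[..., 1] = d_conc
    return np.round(rgb_from_concentrations(conc) * 255).astype(np.uint8)


def test_stain_separation_inverts_rendering():
    rng = np.random.default_rng(0)
    conc = np.zeros((32, 32, 3))
    conc[..., 0] = rng.uniform(0, 1, (32, 32))
    conc[..., 1] = rng.uniform(0, 1, (32, 32))
    recovered = concentrations_from_rgb(rgb_from_concentrations(conc))
    assert np.allclose(recovered[..., :2], conc[..., :2], atol=1e-6)


class TestMaskTissue:
    def test_white_slide_gives_empty_mask(self):
        mask = mask_tissue(_white_slide())
        assert mask.n_pixels == 0
        assert mask.mask.shape == (256, 256)

    def test_mask_overlaps_truth(self, diffuse_slide):
        slide, truth = diffuse_slide
        mask = mask_tissue(slide)
        inter = np.count_nonzero(mask.mask & truth.tissue_mask)
        dice = 2 * inter / (mask.n_pixels + np.count_nonzero(truth.tissue_mask))
        assert dice >= 0.95

    def test_mask_bounded_by_slide(self, hotspot_slide):
        slide, _ = hotspot_slide
        mask = mask_tissue(slide)
        assert mask.mask.shape == slide.shape
        assert mask.n_pixels <= slide.shape[0] * slide.shape[1]


class TestTileSlide:
    def test_ceiling_grid_with_clipped_edges(self):
        slide = _white_slide(100, 100)
        mask = mask_tissue(slide)
        grid = tile_slide(slide, mask, tile_size=64)
        boxes = [(x0, y0, x1, y1) for _, _, x0, y0, x1, y1 in grid.tiles]
        assert boxes == [(0, 0, 64, 64), (64, 0, 100, 64), (0, 64, 64, 100), (64, 64, 100, 100)]

    def test_small_tile_size_rejected(self):
        slide = _white_slide()
        with pytest.raises(ValueError):
            tile_slide(slide, mask_tissue(slide), tile_size=32)

    @pytest.mark.parametrize("tile_size", [96, 128, 256])
    def test_partition_conserves_mask_pixels(self, diffuse_slide, tile_size):
        slide, _ = diffuse_slide
        mask = mask_tissue(slide)
        grid = tile_slide(slide, mask, tile_size)
        total = sum(
            np.count_nonzero(mask.mask[y0:y1, x0:x1])
            for _, _, x0, y0, x1, y1 in grid.tiles
        )
        assert total == mask.n_pixels

    def test_sparse_tissue_drops_tiles(self):
        pixels = np.full((256, 256, 3), 255, dtype=np.uint8)
        corner = _render_tile(np.full((64, 64), 0.7), np.zeros((64, 64)))
        pixels[:64, :64] = corner
        slide = SlideImage(pixels, 0.25, "sparse")
        mask = mask_tissue(slide)
        grid = tile_slide(slide, mask, tile_size=64)
        assert sum(grid.kept_flags) < len(grid.tiles)
        # a tile is dropped exactly when it holds no masked pixels
        for (_, _, x0, y0, x1, y1), kept in zip(grid.tiles, grid.kept_flags):
            assert kept == bool(mask.mask[y0:y1, x0:x1].any())


class TestQuantifyTile:
    def test_empty_mask_yields_zero_counts(self):
        tile = _render_tile(np.zeros((64, 64)), np.zeros((64, 64)))
        q = quantify_tile(tile, np.zeros((64, 64), dtype=bool))
        assert (q.stain_px, q.tissue_px) == (0, 0)

    def test_hematoxylin_only_tissue_is_negative(self):
        tile = _render_tile(np.full((64, 64), 0.7), np.zeros((64, 64)))
        q = quantify_tile(tile, np.ones((64, 64), dtype=bool))
        assert q.stain_px == 0
        assert q.tissue_px == 64 * 64

    def test_dab_block_counted_within_tolerance(self):
        h = np.zeros((100, 100))
        d = np.zeros((100, 100))
        mask = np.zeros((100, 100), dtype=bool)
        mask[:50, :100] = True  # 5000 px tissue
        h[mask] = 0.7
        d[10:30, 10:60] = 0.9  # 1000 px DAB block inside the tissue
        h[10:30, 10:60] = 0.35
        q = quantify_tile(_render_tile(h, d), mask)
        assert abs(q.stain_px - 1000) <= 50
        assert abs(q.tissue_px - 5000) <= 250

    def test_shape_mismatch_rejected(self):
        tile = _render_tile(np.zeros((64, 64)), np.zeros((64, 64)))
        with pytest.raises(ValueError):
            quantify_tile(tile, np.zeros((32, 32), dtype=bool))

    def test_counts_ordering_enforced(self):
        with pytest.raises(ValueError):
            TileQuant(tile_id=(0, 0), stain_px=10, tissue_px=5)


class TestAggregate:
    def test_direct_formula(self):
        quants = [TileQuant((0, 0), 10, 100), TileQuant((0, 1), 0, 100)]
        rec = aggregate_slide(quants, microns_per_pixel=1.0, slide_id="s")
        assert rec.stain_area_um2 == pytest.approx(10.0)
        assert rec.plaque_area_um2 == pytest.approx(200.0)
        assert rec.percent_stain == pytest.approx(5.0)
        assert rec.n_tiles_kept == 2

    def test_area_scales_with_mpp_squared(self):
        quants = [TileQuant((0, 0), 10, 100)]
        rec = aggregate_slide(quants, microns_per_pixel=0.5)
        assert rec.plaque_area_um2 == pytest.approx(100 * 0.25)
        assert rec.percent_stain == pytest.approx(10.0)

    def test_no_tissue_rejected(self):
        with pytest.raises(ValueError):
            aggregate_slide([TileQuant((0, 0), 0, 0)], 1.0)


class TestQuantifySlide:
    @pytest.mark.parametrize("target", [0.1, 0.25, 0.4])
    def test_recovers_true_fraction(self, target):
        cfg = SlideSynthesisConfig(
            target_fraction=target, canvas_size=(512, 512), seed=21
        )
        slide, truth = synthesize_slide(cfg)
        rec = quantify_slide(slide, QuantParams(tile_size=256))
        assert abs(rec.percent_stain / 100 - truth.true_fraction) <= 0.05 * target + 0.01

    def test_oracle_equivalence_on_noise_free_slide(self):
        cfg = SlideSynthesisConfig(
            target_fraction=0.3, canvas_size=(384, 384), seed=5,
            noise_sigma=0.0, illumination_amplitude=0.0,
        )
        slide, truth = synthesize_slide(cfg)
        params = QuantParams(tile_size=128, min_object_px=0)
        from glycoquant.wsi_quant import mask_tissue as mt, tile_slide as ts

        mask = mt(slide, params)
        grid = ts(slide, mask, params.tile_size)
        for (r, c, x0, y0, x1, y1), kept in zip(grid.tiles, grid.kept_flags):
            if not kept:
                continue
            q = quantify_tile(slide.pixels[y0:y1, x0:x1], mask.mask[y0:y1, x0:x1], params)
            assert q.stain_px == int(truth.stain_mask[y0:y1, x0:x1].sum())

    def test_tiling_invariance(self):
        cfg = SlideSynthesisConfig(target_fraction=0.25, canvas_size=(640, 640), seed=13)
        slide, _ = synthesize_slide(cfg)
        pcts = [
            quantify_slide(slide, QuantParams(tile_size=t)).percent_stain
            for t in (128, 256, 512)
        ]
        assert max(pcts) - min(pcts) < 0.5

    def test_two_sections_pool_like_separate_slides(self):
        cfg = SlideSynthesisConfig(
            target_fraction=0.3, n_sections=2, canvas_size=(512, 512), seed=17
        )
        slide, _ = synthesize_slide(cfg)
        whole = quantify_slide(slide, QuantParams(tile_size=256))
        halves = []
        for sl in (np.s_[:, :256], np.s_[:, 256:]):
            half = SlideImage(slide.pixels[sl].copy(), slide.microns_per_pixel, "half")
            halves.append(quantify_slide(half, QuantParams(tile_size=256)))
        stain = sum(h.stain_area_um2 for h in halves)
        plaque = sum(h.plaque_area_um2 for h in halves)
        pooled = 100 * stain / plaque
        assert abs(pooled - whole.percent_stain) <= 0.5

    def test_all_white_slide_rejected(self):
        with pytest.raises(ValueError):
            quantify_slide(_white_slide())


class TestSpearmanValidation:
    def test_identity_and_antisymmetry(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert spearman_validation(x, x) == pytest.approx(1.0)
        assert spearman_validation(x, x[::-1]) == pytest.approx(-1.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            spearman_validation([1.0, 2.0], [1.0, 2.0])
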