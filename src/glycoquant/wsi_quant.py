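"""Whole-slide DAB-positive area quantification.

The measurement chain mirrors the standard automated IHC workflow for
scanned plaque sections:

1. **mask** — separate tissue from near-white glass background on the
   saturation channel, with morphological cleanup;
2. **tile** — cover the slide with a row-major grid of half-open pixel
   boxes and drop tiles that contain no tissue;
3. **quantify** — per tile, deconvolve the RGB image into hematoxylin and
   DAB optical densities, threshold the DAB channel, remove speckle
   objects, and count positive pixels inside the tissue mask;
4. **aggregate** — convert pixel counts to μm² with the slide calibration
   and report the stained area as a percent of the total plaque area,
   ``100 × stained / plaque``.

Multiple sections on one slide are pooled: the percent is taken over the
total tissue area regardless of how many sections contribute to it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_holes, remove_small_objects

from .stain import concentrations_from_rgb
from .synthetic_slides import SlideImage

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QuantParams:
    """Tunable parameters of the quantification chain.

    dab_od_threshold is in base-10 optical-density concentration units of
    the unit DAB vector; 0.15 separates genuine chromogen from counterstain
    crosstalk and sensor noise on typical brightfield material.
    """

    tile_size: int = 512
    dab_od_threshold: float = 0.15
    min_object_px: int = 30
    saturation_threshold: float | None = None  # None = Otsu with a 0.04 floor
    saturation_floor: float = 0.04
    min_tissue_object_px: int = 500
    max_hole_px: int = 500
    microns_per_pixel: float | None = None  # None = take it from the slide


@dataclass
class TissueMask:
    mask: np.ndarray
    source_slide_id: str = ""

    def __post_init__(self) -> None:
        if self.mask.dtype != bool:
            raise ValueError("tissue mask must be boolean")

    @property
    def n_pixels(self) -> int:
        return int(np.count_nonzero(self.mask))


@dataclass
class TileGrid:
    """Row-major half-open tile boxes covering a slide.

    Each entry of ``tiles`` is (row, col, x0, y0, x1, y1) with 0-based pixel
    coordinates and boxes [y0, y1) × [x0, x1), edge boxes clipped to the
    slide bounds.  ``kept_flags[i]`` is False iff box i holds no tissue.
    """

    tile_size: int
    tiles: list[tuple[int, int, int, int, int, int]]
    kept_flags: list[bool]
    slide_shape: tuple[int, int]


@dataclass
class TileQuant:
    tile_id: tuple[int, int]
    stain_px: int
    tissue_px: int

    def __post_init__(self) -> None:
        if not 0 <= self.stain_px <= self.tissue_px:
            raise ValueError("need 0 <= stain_px <= tissue_px")


@dataclass
class StainQuantRecord:
    """Per-slide result: areas in μm² and the percent-of-plaque measure."""

    slide_id: str
    stain_area_um2: float
    plaque_area_um2: float
    percent_stain: float
    n_tiles_kept: int

    def __post_init__(self) -> None:
        if self.stain_area_um2 > self.plaque_area_um2 + 1e-9:
            raise ValueError("stained area cannot exceed plaque area")


def mask_tissue(slide: SlideImage, params: QuantParams = QuantParams()) -> TissueMask:
    """Mask non-background pixels of a brightfield slide.

    Glass background is near-white and therefore nearly unsaturated; tissue
    (hematoxylin blue or DAB brown) carries color.  The saturation channel
    is thresholded by Otsu with an absolute floor so a blank slide yields an
    empty mask, then small speckles are removed and small holes filled.
    An empty mask is a legal output; downstream aggregation rejects it.
    """
    hsv = rgb2hsv(slide.pixels)
    sat = hsv[..., 1]
    if params.saturation_threshold is not None:
        thr = params.saturation_threshold
    else:
        try:
            thr = float(threshold_otsu(sat))
        except ValueError:  # constant image
            thr = params.saturation_floor
        thr = max(thr, params.saturation_floor)
    mask = sat > thr
    if params.min_tissue_object_px > 0:
        mask = remove_small_objects(mask, max_size=params.min_tissue_object_px - 1)
    if params.max_hole_px > 0:
        mask = remove_small_holes(mask, max_size=params.max_hole_px - 1)
    return TissueMask(mask=mask, source_slide_id=slide.slide_id)


def tile_slide(slide: SlideImage, mask: TissueMask, tile_size: int = 512) -> TileGrid:
    """Cover the slide with a grid of half-open boxes; flag tissue-free tiles."""
    if tile_size < 64:
        raise ValueError("tile_size must be >= 64 px")
    h, w = slide.shape
    if mask.mask.shape != (h, w):
        raise ValueError("mask shape must match slide shape")
    tiles = []
    kept = []
    n_rows = -(-h // tile_size)
    n_cols = -(-w // tile_size)
    for r in range(n_rows):
        for c in range(n_cols):
            y0, x0 = r * tile_size, c * tile_size
            y1, x1 = min(y0 + tile_size, h), min(x0 + tile_size, w)
            tiles.append((r, c, x0, y0, x1, y1))
            kept.append(bool(mask.mask[y0:y1, x0:x1].any()))
    return TileGrid(tile_size=tile_size, tiles=tiles, kept_flags=kept, slide_shape=(h, w))


def quantify_tile(
    tile_pixels: np.ndarray,
    tile_mask: np.ndarray,
    params: QuantParams = QuantParams(),
    tile_id: tuple[int, int] = (0, 0),
) -> TileQuant:
    """Count DAB-positive pixels within the masked tissue of one tile."""
    if tile_pixels.shape[:2] != tile_mask.shape:
        raise ValueError("tile and mask shapes must agree")
    tissue_px = int(np.count_nonzero(tile_mask))
    if tissue_px == 0:
        return TileQuant(tile_id=tile_id, stain_px=0, tissue_px=0)
    dab = concentrations_from_rgb(tile_pixels)[..., 1]
    positive = dab > params.dab_od_threshold
    if params.min_object_px > 0:
        positive = remove_small_objects(positive, max_size=params.min_object_px - 1)
    stain_px = int(np.count_nonzero(positive & tile_mask))
    return TileQuant(tile_id=tile_id, stain_px=stain_px, tissue_px=tissue_px)


def aggregate_slide(
    tile_quants: list[TileQuant],
    microns_per_pixel: float,
    slide_id: str = "",
) -> StainQuantRecord:
    """Pool tile counts into areas and the percent-of-plaque measure."""
    if microns_per_pixel <= 0:
        raise ValueError("microns_per_pixel must be > 0")
    stain_px = sum(t.stain_px for t in tile_quants)
    tissue_px = sum(t.tissue_px for t in tile_quants)
    if tissue_px == 0:
        raise ValueError("no plaque measured: all tiles are tissue-free")
    px_area = microns_per_pixel**2
    stain_area = stain_px * px_area
    plaque_area = tissue_px * px_area
    return StainQuantRecord(
        slide_id=slide_id,
        stain_area_um2=stain_area,
        plaque_area_um2=plaque_area,
        percent_stain=100.0 * stain_area / plaque_area,
        n_tiles_kept=sum(1 for t in tile_quants if t.tissue_px > 0),
    )


def quantify_slide(
    slide: SlideImage, params: QuantParams = QuantParams()
) -> StainQuantRecord:
    """Full chain: mask → tile → per-tile stain counting → aggregation."""
    mask = mask_tissue(slide, params)
    grid = tile_slide(slide, mask, params.tile_size)
    logger.info(
        "slide %s: %d tissue px, %d/%d tiles kept",
        slide.slide_id,
        mask.n_pixels,
        sum(grid.kept_flags),
        len(grid.tiles),
    )
    quants = []
    for (r, c, x0, y0, x1, y1), kept in zip(grid.tiles, grid.kept_flags):
        if not kept:
            continue
        quants.append(
            quantify_tile(
                slide.pixels[y0:y1, x0:x1],
                mask.mask[y0:y1, x0:x1],
                params,
                tile_id=(r, c),
            )
        )
    mpp = params.microns_per_pixel or slide.microns_per_pixel
    record = aggregate_slide(quants, mpp, slide_id=slide.slide_id)
    logger.info(
        "slide %s: %.1f%% stained (%.0f / %.0f μm²)",
        slide.slide_id,
        record.percent_stain,
        record.stain_area_um2,
        record.plaque_area_um2,
    )
    return record


def spearman_validation(auto: list[float], reference: list[float]) -> float:
    """Spearman rank correlation (average ranks for ties) of two measurement sets."""
    auto = np.asarray(auto, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if auto.shape != reference.shape or auto.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if auto.size < 3:
        raise ValueError("need at least 3 paired measurements")
    rho = spearmanr(auto, reference).statistic
    return float(rho)
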