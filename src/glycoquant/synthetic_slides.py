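"""Synthetic brightfield H-DAB plaque slides with pixel-exact ground truth.

Generates images that look like scanned glycophorin-C-stained carotid plaque
sections: near-white glass background, one or more bluish
hematoxylin-counterstained tissue sections, and brown DAB-positive regions
whose total area is a controlled fraction of the tissue.  Every slide comes
with exact binary tissue and stain masks, so the quantification pipeline can
be validated without any real whole-slide image.

Two spatial patterns are supported, mirroring the morphologies seen in real
plaques: ``diffuse`` staining scattered across the section in many small
patches, and ``hotspot`` staining concentrated in a few large regions near a
section core.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image
from scipy.ndimage import gaussian_filter

from .stain import rgb_from_concentrations

PATTERNS = ("diffuse", "hotspot")


@dataclass(frozen=True)
class SlideSynthesisConfig:
    """Parameters of one synthetic slide.

    target_fraction is the requested stained share of the tissue area, in
    [0, 0.8]; fractions above 0.8 are rejected as unphysical coverage.
    Densities are optical-density multiples of the unit stain vectors.
    """

    target_fraction: float = 0.25
    n_sections: int = 1
    pattern: str = "diffuse"
    canvas_size: tuple[int, int] = (2048, 2048)
    microns_per_pixel: float = 0.25
    noise_sigma: float = 4.0 / 255.0
    illumination_amplitude: float = 0.03
    hematoxylin_density: float = 0.7
    dab_density: float = 0.9
    hematoxylin_under_dab: float = 0.35
    texture_amplitude: float = 0.08
    seed: int = 0
    slide_id: str | None = None

    def validate(self) -> None:
        if not 0.0 <= self.target_fraction <= 0.8:
            raise ValueError(
                f"target_fraction must be in [0, 0.8], got {self.target_fraction}"
            )
        if self.n_sections < 1:
            raise ValueError("n_sections must be >= 1")
        if self.pattern not in PATTERNS:
            raise ValueError(f"pattern must be one of {PATTERNS}")
        h, w = self.canvas_size
        if h <= 0 or w <= 0:
            raise ValueError("canvas_size must be positive")
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class SectionLayout:
    """Disjoint binary masks of the tissue sections on one canvas."""

    section_masks: list[np.ndarray]
    canvas_size: tuple[int, int]
    microns_per_pixel: float

    def __post_init__(self) -> None:
        if not self.section_masks:
            raise ValueError("at least one section is required")
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be > 0")
        total = np.zeros(self.canvas_size, dtype=int)
        for m in self.section_masks:
            if m.shape != tuple(self.canvas_size):
                raise ValueError("section mask shape must match canvas")
            if not m.any():
                raise ValueError("every section must contain >= 1 pixel")
            total += m.astype(int)
        if (total > 1).any():
            raise ValueError("sections must be pairwise disjoint")


@dataclass
class GroundTruthSlide:
    """Exact truth for a synthetic slide: masks and realized fraction."""

    tissue_mask: np.ndarray
    stain_mask: np.ndarray
    true_fraction: float
    pattern: str
    sections: SectionLayout | None = None

    def __post_init__(self) -> None:
        if (self.stain_mask & ~self.tissue_mask).any():
            raise ValueError("stain_mask must be a subset of tissue_mask")
        n_tissue = int(np.count_nonzero(self.tissue_mask))
        n_stain = int(np.count_nonzero(self.stain_mask))
        if n_tissue == 0:
            raise ValueError("tissue_mask must be non-empty")
        exact = n_stain / n_tissue
        if abs(exact - self.true_fraction) > 1e-12:
            raise ValueError("true_fraction must equal |stain| / |tissue|")


@dataclass
class SlideImage:
    """An RGB brightfield image with its physical pixel calibration."""

    pixels: np.ndarray
    microns_per_pixel: float
    slide_id: str = ""
    stain_label: str = "glycophorin_c"

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be H×W×3")
        if self.pixels.shape[0] <= 0 or self.pixels.shape[1] <= 0:
            raise ValueError("image must be non-empty")
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


def _section_layout(rng: np.random.Generator, config: SlideSynthesisConfig) -> SectionLayout:
    """Random blob-like sections, one per vertical strip (hence disjoint)."""
    h, w = config.canvas_size
    n = config.n_sections
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    masks = []
    for s in range(n):
        x_lo = s * w // n
        x_hi = (s + 1) * w // n if s < n - 1 else w
        sw = x_hi - x_lo
        cx = rng.uniform(x_lo + 0.40 * sw, x_lo + 0.60 * sw)
        cy = rng.uniform(0.40 * h, 0.60 * h)
        rx = 0.30 * sw * rng.uniform(0.85, 1.0)
        ry = 0.34 * h * rng.uniform(0.80, 1.0)
        implicit = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
        wobble = gaussian_filter(rng.standard_normal((h, w)), sigma=max(4.0, h / 16.0))
        wobble /= np.abs(wobble).max() + 1e-12
        mask = (implicit + 0.55 * wobble) < 1.0
        mask &= (xx >= x_lo) & (xx < x_hi)
        if not mask.any():  # degenerate canvas; fall back to the bare ellipse
            mask = (implicit < 1.0) & (xx >= x_lo) & (xx < x_hi)
        masks.append(mask)
    return SectionLayout(masks, (h, w), config.microns_per_pixel)


def _stain_field(
    rng: np.random.Generator,
    shape: tuple[int, int],
    layout: SectionLayout,
    pattern: str,
) -> np.ndarray:
    """Scalar field whose upper level sets define the stained region."""
    h, w = shape
    if pattern == "diffuse":
        # many mid-sized patches scattered over the tissue
        return gaussian_filter(rng.standard_normal(shape), sigma=max(3.0, h / 48.0))
    # hotspot: a few large blobs near a core point of each section
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    field = np.full(shape, -np.inf)
    for mask in layout.section_masks:
        ys, xs = np.nonzero(mask)
        cy, cx = ys.mean(), xs.mean()
        j = rng.integers(len(ys))
        cy = 0.6 * cy + 0.4 * ys[j]
        cx = 0.6 * cx + 0.4 * xs[j]
        dist = np.hypot(yy - cy, xx - cx)
        field = np.maximum(field, -dist / (0.25 * h))
    rough = gaussian_filter(rng.standard_normal(shape), sigma=max(3.0, h / 32.0))
    rough /= np.abs(rough).max() + 1e-12
    return field + 0.35 * rough


def _top_k_mask(field: np.ndarray, tissue: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask of exactly the k highest-field tissue pixels."""
    out = np.zeros_like(tissue)
    if k <= 0:
        return out
    vals = field[tissue]
    if k >= vals.size:
        return tissue.copy()
    kth = np.partition(vals, vals.size - k)[vals.size - k]
    sel = tissue & (field >= kth)
    excess = int(np.count_nonzero(sel)) - k
    if excess > 0:  # float ties are rare; drop deterministic surplus
        ties = np.flatnonzero((field == kth).ravel() & sel.ravel())
        sel.ravel()[ties[:excess]] = False
    return sel


def synthesize_slide(
    config: SlideSynthesisConfig,
) -> tuple[SlideImage, GroundTruthSlide]:
    """Render one synthetic H-DAB slide plus its exact ground truth.

    The stained-pixel count is set to round(target_fraction × tissue area),
    so the realized ``true_fraction`` matches the target to within one pixel.
    Identical (config, seed) pairs reproduce byte-identical pixel arrays.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.canvas_size

    layout = _section_layout(rng, config)
    tissue = np.zeros((h, w), dtype=bool)
    for m in layout.section_masks:
        tissue |= m

    n_tissue = int(np.count_nonzero(tissue))
    k = int(round(config.target_fraction * n_tissue))
    field = _stain_field(rng, (h, w), layout, config.pattern)
    stain = _top_k_mask(field, tissue, k)

    # stain concentration maps with mild multiplicative texture
    texture = gaussian_filter(rng.standard_normal((h, w)), sigma=max(2.0, h / 64.0))
    texture /= np.abs(texture).max() + 1e-12
    texture = 1.0 + config.texture_amplitude * texture

    conc = np.zeros((h, w, 3))
    conc[..., 0] = np.where(tissue, config.hematoxylin_density, 0.0)
    conc[..., 0][stain] = config.hematoxylin_under_dab
    conc[..., 1][stain] = config.dab_density
    conc[..., :2] *= texture[..., None]

    rgb = rgb_from_concentrations(conc)

    if config.illumination_amplitude > 0:
        theta = rng.uniform(0, 2 * np.pi)
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        plane = (xx / w - 0.5) * np.cos(theta) + (yy / h - 0.5) * np.sin(theta)
        rgb = rgb * (1.0 + config.illumination_amplitude * plane)[..., None]
    if config.noise_sigma > 0:
        rgb = rgb + rng.normal(0.0, config.noise_sigma, rgb.shape)

    pixels = np.round(np.clip(rgb, 0.0, 1.0) * 255.0).astype(np.uint8)

    slide_id = config.slide_id or f"synthetic_{config.pattern}_{config.seed}"
    slide = SlideImage(pixels, config.microns_per_pixel, slide_id)
    truth = GroundTruthSlide(
        tissue_mask=tissue,
        stain_mask=stain,
        true_fraction=int(np.count_nonzero(stain)) / n_tissue,
        pattern=config.pattern,
        sections=layout,
    )
    return slide, truth


def synthesize_validation_tiles(
    n_tiles: int,
    fraction_grid: list[float],
    seed: int,
    tile_size: int = 512,
    microns_per_pixel: float = 0.25,
    pattern: str = "diffuse",
) -> list[tuple[SlideImage, float]]:
    """One single-section tile per requested stained fraction.

    Mirrors the manual-versus-automated validation design: a ladder of
    tiles whose true stained fractions span the requested grid, against
    which pipeline estimates can be rank-correlated.  Because each tile's
    stained pixel count is exact to rounding, realized fractions are
    non-decreasing along an ascending grid.
    """
    fraction_grid = list(fraction_grid)
    if not fraction_grid:
        raise ValueError("fraction_grid must not be empty")
    if n_tiles != len(fraction_grid):
        raise ValueError("n_tiles must equal len(fraction_grid)")
    if any(b < a for a, b in zip(fraction_grid, fraction_grid[1:])):
        raise ValueError("fraction_grid must be sorted ascending")

    children = np.random.SeedSequence(seed).spawn(n_tiles)
    out = []
    for i, (frac, child) in enumerate(zip(fraction_grid, children)):
        cfg = SlideSynthesisConfig(
            target_fraction=frac,
            n_sections=1,
            pattern=pattern,
            canvas_size=(tile_size, tile_size),
            microns_per_pixel=microns_per_pixel,
            seed=int(child.generate_state(1)[0] % (2**31)),
            slide_id=f"validation_tile_{i:02d}",
        )
        slide, truth = synthesize_slide(cfg)
        out.append((slide, truth.true_fraction))
    return out


# ---------------------------------------------------------------------------
# disk I/O: single-resolution TIFF + PNG truth masks + JSON sidecar


def write_slide(
    out_dir: str | Path,
    slide: SlideImage,
    truth: GroundTruthSlide | None = None,
    config: SlideSynthesisConfig | None = None,
) -> Path:
    """Write ``<id>.tiff`` plus truth-mask PNGs and a JSON sidecar.

    Returns the path of the TIFF.  The sidecar records the calibration and,
    when truth is given, the exact stained fraction, so downstream accuracy
    checks never need the in-memory objects.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tiff_path = out_dir / f"{slide.slide_id}.tiff"
    tifffile.imwrite(tiff_path, slide.pixels)
    meta = {
        "slide_id": slide.slide_id,
        "stain_label": slide.stain_label,
        "microns_per_pixel": slide.microns_per_pixel,
    }
    if truth is not None:
        Image.fromarray((truth.tissue_mask * 255).astype(np.uint8)).save(
            out_dir / f"{slide.slide_id}_tissue_mask.png"
        )
        Image.fromarray((truth.stain_mask * 255).astype(np.uint8)).save(
            out_dir / f"{slide.slide_id}_stain_mask.png"
        )
        meta["true_fraction"] = truth.true_fraction
        meta["pattern"] = truth.pattern
    if config is not None:
        meta["config"] = asdict(config)
    (out_dir / f"{slide.slide_id}.json").write_text(json.dumps(meta, indent=2))
    return tiff_path


def read_slide(path: str | Path, microns_per_pixel: float | None = None) -> SlideImage:
    """Read a TIFF/PNG slide; calibration comes from the JSON sidecar if present."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        pixels = tifffile.imread(path)
    else:
        pixels = np.asarray(Image.open(path).convert("RGB"))
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    mpp = microns_per_pixel or meta.get("microns_per_pixel")
    if mpp is None:
        raise ValueError(f"no microns_per_pixel for {path}; pass it explicitly")
    return SlideImage(
        pixels=np.ascontiguousarray(pixels[..., :3]),
        microns_per_pixel=float(mpp),
        slide_id=meta.get("slide_id", path.stem),
        stain_label=meta.get("stain_label", "glycophorin_c"),
    )
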