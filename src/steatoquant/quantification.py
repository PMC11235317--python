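"""Percent-steatosis estimates per tile, per field image, and per slide.

The denominator is always tissue pixels (with fat counting as tissue), never
whole-image pixels, so a score does not depend on how much empty slide
happens to be in frame.  A slide's score is the unweighted arithmetic mean
of its field fractions (the pooled-pixel ratio is carried alongside as a
diagnostic), and a capture stability filter rejects unsharp or nearly
tissue-free fields before they enter the average.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .config import RunConfig
from .errors import ContractError, InvalidEstimateError, NoTissueError
from .segmentation import classical_backend, compute_tissue_mask, segment_tiles
from .tiling import stitch_masks, tile_image
from .types import BinaryMask, FieldImage

logger = logging.getLogger(__name__)

SHARPNESS_EPS = 1e-6
MIN_TISSUE_AREA_FRACTION = 0.05
HIGH_PASS_KERNEL = np.array([[-1.0, -1.0, -1.0], [-1.0, 8.0, -1.0], [-1.0, -1.0, -1.0]])


@dataclass(frozen=True)
class TileStat:
    """Fat / tissue pixel counts within one tile window (source pixels only)."""

    row: int
    col: int
    fat_px: int
    tissue_px: int

    @property
    def included(self) -> bool:
        """Tiles with no tissue are excluded from per-tile statistics."""
        return self.tissue_px > 0

    @property
    def fraction(self) -> float | None:
        return self.fat_px / self.tissue_px if self.tissue_px > 0 else None


@dataclass(frozen=True)
class SteatosisEstimate:
    """Percent-steatosis estimate for one field image."""

    fat_px: int
    tissue_px: int
    fraction: float
    per_tile: tuple[TileStat, ...] = ()
    source_id: str = ""

    def __post_init__(self):
        if self.fat_px > self.tissue_px:
            raise ContractError("fat_px must be <= tissue_px")

    @property
    def n_tiles(self) -> int:
        return len(self.per_tile)

    @property
    def per_tile_fractions(self) -> list[float]:
        return [t.fraction for t in self.per_tile if t.included]


@dataclass(frozen=True)
class SlideEstimate:
    """Aggregate over the field images sampled from one slide.

    ``slide_fraction`` is the arithmetic mean of field fractions;
    ``pooled_fraction`` is the pooled pixel ratio sum(fat)/sum(tissue),
    reported as a diagnostic.  When every field is rejected the estimate is
    flagged invalid and both fractions are None.
    """

    field_estimates: tuple[SteatosisEstimate, ...]
    slide_fraction: float | None
    pooled_fraction: float | None
    rejected_fields: tuple[tuple[str, str], ...] = ()
    invalid_reason: str | None = None

    @property
    def n_fields(self) -> int:
        return len(self.field_estimates)

    @property
    def valid(self) -> bool:
        return self.n_fields >= 1 and self.invalid_reason is None


def percent_steatosis(
    fat: BinaryMask,
    tissue: BinaryMask,
    per_tile: tuple[TileStat, ...] = (),
    source_id: str = "",
) -> SteatosisEstimate:
    """Exact pixel-count fraction fat/tissue for one mask pair.

    Raises :class:`NoTissueError` when the tissue mask is empty and
    :class:`ContractError` when fat is not a subset of tissue (violations
    are an error, never silently clipped).
    """
    if fat.shape != tissue.shape:
        raise ContractError(f"mask shapes differ: {fat.shape} vs {tissue.shape}")
    if not fat.is_subset_of(tissue):
        raise ContractError("fat mask is not a subset of the tissue mask")
    fat_px = fat.count
    tissue_px = tissue.count
    if tissue_px == 0:
        raise NoTissueError("no tissue in field")
    return SteatosisEstimate(
        fat_px=fat_px,
        tissue_px=tissue_px,
        fraction=fat_px / tissue_px,
        per_tile=per_tile,
        source_id=source_id,
    )


def quantify_field(image: FieldImage, config: RunConfig | None = None) -> SteatosisEstimate:
    """Full per-field pipeline: tissue mask -> tiling -> per-tile fat masks -> stitch -> count.

    The field fraction is computed over the tile-covered region only, so it
    equals sum(tile fat)/sum(tile tissue) over included tiles regardless of
    the edge policy.
    """
    cfg = config or RunConfig()
    tissue = compute_tissue_mask(image, cfg.segmenter)
    grid = tile_image(image, cfg.tile_size, cfg.tile_policy)
    tiles = [
        FieldImage(t, pixel_size_um=image.pixel_size_um, source_id=f"{image.source_id}#tile{i}")
        for i, t in enumerate(grid.extract(image.pixels))
    ]
    backend = classical_backend(cfg.segmenter, per_tile=True)
    tile_masks = segment_tiles(grid, tiles, backend)
    stitched = stitch_masks(grid, tile_masks, "fat")
    fat_vals = stitched.values & tissue.values
    coverage = grid.coverage_mask()
    tissue_vals = tissue.values & coverage
    per_tile = []
    s = grid.tile_size
    for t in grid.tiles:
        y1 = min(t.y0 + s, grid.source_height)
        x1 = min(t.x0 + s, grid.source_width)
        if t.y0 >= y1 or t.x0 >= x1:
            per_tile.append(TileStat(t.row, t.col, 0, 0))
            continue
        fat_ct = int(np.count_nonzero(fat_vals[t.y0 : y1, t.x0 : x1]))
        tis_ct = int(np.count_nonzero(tissue_vals[t.y0 : y1, t.x0 : x1]))
        per_tile.append(TileStat(t.row, t.col, fat_ct, tis_ct))
    estimate = percent_steatosis(
        BinaryMask(fat_vals, "fat"),
        BinaryMask(tissue_vals, "tissue"),
        per_tile=tuple(per_tile),
        source_id=image.source_id,
    )
    logger.info(
        "field %s: fat_px=%d tissue_px=%d fraction=%.4f (%d tiles)",
        image.source_id, estimate.fat_px, estimate.tissue_px, estimate.fraction, estimate.n_tiles,
    )
    for t in per_tile:
        logger.debug("  tile (%d,%d): fat=%d tissue=%d", t.row, t.col, t.fat_px, t.tissue_px)
    return estimate


def sharpness_score(image: FieldImage) -> float:
    """Focus metric: variance of a 3x3 high-pass response on the luminance plane,
    normalized by mean luminance + epsilon.  Zero for a constant image."""
    lum = image.luminance()
    resp = ndimage.convolve(lum, HIGH_PASS_KERNEL, mode="reflect")
    return float(resp.var() / (lum.mean() + SHARPNESS_EPS))


def stability_filter(
    images: list[FieldImage],
    tau_F: float | None = None,
    config: RunConfig | None = None,
) -> tuple[list[FieldImage], list[tuple[str, str]]]:
    """Capture stability filter: reject unsharp fields and fields with
    almost no tissue (< 5% of pixels).  Returns (accepted, rejected with reasons)."""
    if not images:
        raise ContractError("stability_filter needs at least one image")
    cfg = config or RunConfig()
    threshold = cfg.tau_F if tau_F is None else tau_F
    if threshold < 0:
        raise ContractError("tau_F must be >= 0")
    accepted: list[FieldImage] = []
    rejected: list[tuple[str, str]] = []
    for img in images:
        if sharpness_score(img) < threshold:
            rejected.append((img.source_id, "unsharp"))
            continue
        tissue = compute_tissue_mask(img, cfg.segmenter)
        if tissue.count < MIN_TISSUE_AREA_FRACTION * img.height * img.width:
            rejected.append((img.source_id, "insufficient tissue"))
            continue
        accepted.append(img)
    return accepted, rejected


def quantify_slide(images: list[FieldImage], config: RunConfig | None = None) -> SlideEstimate:
    """Stability-filter the sampled fields, quantify each survivor, and average.

    All-fields-rejected yields an invalid (but returned, machine-readable)
    estimate rather than an exception.
    """
    cfg = config or RunConfig()
    accepted, rejected = stability_filter(images, config=cfg)
    estimates: list[SteatosisEstimate] = []
    for img in accepted:
        try:
            estimates.append(quantify_field(img, cfg))
        except NoTissueError:
            rejected.append((img.source_id, "no tissue in field"))
    if not estimates:
        return SlideEstimate(
            field_estimates=(),
            slide_fraction=None,
            pooled_fraction=None,
            rejected_fields=tuple(rejected),
            invalid_reason="all fields rejected",
        )
    fractions = [e.fraction for e in estimates]
    pooled_num = sum(e.fat_px for e in estimates)
    pooled_den = sum(e.tissue_px for e in estimates)
    return SlideEstimate(
        field_estimates=tuple(estimates),
        slide_fraction=float(np.mean(fractions)),
        pooled_fraction=pooled_num / pooled_den,
        rejected_fields=tuple(rejected),
    )
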