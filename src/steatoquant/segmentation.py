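"""Per-pixel fat-vacuole classification.

The reference backend is a fully classical pipeline: fat vacuoles and empty
slide background are bright and nearly unsaturated on an H&E frozen section,
while stained tissue is pink (saturated) and darker.  Candidate bright
regions are cleaned morphologically and then filtered by area and
circularity, which is what rejects bright-but-elongated tear artifacts
without scoring them as steatosis.

The backend contract is a plain callable ``FieldImage -> binary mask of the
same shape``, so a learned per-tile model can be slotted into
:func:`segment_tiles` in place of the classical reference.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .errors import ContractError
from .tiling import TileGrid
from .types import BinaryMask, FieldImage

EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)

Backend = Callable[[FieldImage], "BinaryMask | np.ndarray"]


@dataclass(frozen=True)
class SegmenterConfig:
    """Parameters of the classical reference segmenter.

    tau_L / tau_S
        Luminance floor and saturation ceiling defining "bright" candidate
        pixels (both in [0, 1]).
    open_radius_px / close_radius_px
        Radii of the morphological opening (fat candidates) and closing
        (tissue mask), in pixels.
    area_min_px / area_max_px, tau_C
        Component filters: retained fat components must have an area in
        ``[area_min_px, area_max_px]`` and circularity 4*pi*A/P**2 >= tau_C.
    remove_border_background
        Whether bright components touching the image border are treated as
        empty-slide background and removed before component analysis.
        Disabled when the segmenter runs on interior tiles, where the
        field-level tissue mask already accounts for background.
    """

    tau_L: float = 0.82
    tau_S: float = 0.12
    open_radius_px: int = 1
    close_radius_px: int = 5
    area_min_px: int = 30
    area_max_px: int = 50_000
    # tau_C separates the two bright-object classes: elongated tears score
    # below ~0.25 on the boundary-pixel estimator while vacuoles and merged
    # vacuole pairs/triples stay above ~0.6; 0.4 splits them with margin.
    tau_C: float = 0.4
    remove_border_background: bool = True
    # Bright border-connected regions count as empty-slide background only
    # when they are macroscopic; a vacuole cut by the frame edge is small.
    min_background_area_frac: float = 0.02

    def __post_init__(self):
        if not (0.0 < self.tau_L < 1.0) or not (0.0 < self.tau_S < 1.0):
            raise ContractError("tau_L and tau_S must lie strictly in (0, 1)")
        if not (0.0 < self.tau_C <= 1.0):
            raise ContractError("tau_C must lie in (0, 1]")
        if self.area_min_px >= self.area_max_px:
            raise ContractError("area_min_px must be < area_max_px")
        if self.open_radius_px < 0 or self.close_radius_px < 0:
            raise ContractError("morphology radii must be >= 0")
        if not (0.0 <= self.min_background_area_frac <= 1.0):
            raise ContractError("min_background_area_frac must lie in [0, 1]")


def bright_pixel_map(image: FieldImage, cfg: SegmenterConfig) -> np.ndarray:
    """Candidate map: luminance >= tau_L and saturation <= tau_S."""
    return (image.luminance() >= cfg.tau_L) & (image.saturation() <= cfg.tau_S)


def _border_connected(mask: np.ndarray, min_area: int = 0) -> np.ndarray:
    """Subset of ``mask`` 8-connected to the image border (components >= min_area)."""
    labels, n = ndimage.label(mask, structure=EIGHT_CONNECTED)
    if n == 0:
        return np.zeros_like(mask)
    border_labels = np.unique(
        np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    )
    border_labels = border_labels[border_labels > 0]
    if min_area > 0 and border_labels.size:
        areas = np.bincount(labels.ravel(), minlength=n + 1)
        border_labels = border_labels[areas[border_labels] >= min_area]
    if border_labels.size == 0:
        return np.zeros_like(mask)
    return np.isin(labels, border_labels)


def _pad_closing(mask: np.ndarray, radius: int) -> np.ndarray:
    """Binary closing with edge-replicated padding so borders are not shaved."""
    if radius <= 0:
        return mask
    padded = np.pad(mask, radius, mode="edge")
    closed = ndimage.binary_closing(padded, structure=disk(radius).astype(bool))
    return closed[radius:-radius, radius:-radius]


def _pad_opening(mask: np.ndarray, radius: int) -> np.ndarray:
    if radius <= 0:
        return mask
    padded = np.pad(mask, radius, mode="edge")
    opened = ndimage.binary_opening(padded, structure=disk(radius).astype(bool))
    return opened[radius:-radius, radius:-radius]


def component_metrics(labels: np.ndarray, n_labels: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Areas, boundary-pixel perimeters and clipped circularities per label.

    The perimeter estimator counts boundary pixels (pixels of the component
    with at least one 4-neighbour outside it).  Circularity 4*pi*A/P**2 is
    clipped to <= 1; rasterization makes compact discs saturate at 1.
    Index 0 of each returned array corresponds to the background label.
    """
    areas = np.bincount(labels.ravel(), minlength=n_labels + 1)
    padded = np.pad(labels, 1, mode="constant")
    core = padded[1:-1, 1:-1]
    boundary = np.zeros(core.shape, dtype=bool)
    boundary |= core != padded[:-2, 1:-1]
    boundary |= core != padded[2:, 1:-1]
    boundary |= core != padded[1:-1, :-2]
    boundary |= core != padded[1:-1, 2:]
    boundary &= core > 0
    perims = np.bincount(core[boundary], minlength=n_labels + 1)
    circ = np.zeros(n_labels + 1, dtype=np.float64)
    nonzero = perims > 0
    circ[nonzero] = np.minimum(
        1.0, 4.0 * math.pi * areas[nonzero] / perims[nonzero].astype(np.float64) ** 2
    )
    return areas, perims, circ


def compute_tissue_mask(image: FieldImage, cfg: SegmenterConfig | None = None) -> BinaryMask:
    """Separate stained tissue from bright empty-slide background.

    Bright pixels whose 8-connected component touches the image border are
    background; tissue is the complement, morphologically closed and
    hole-filled, so interior bright regions (candidate vacuoles) remain
    tissue.
    """
    cfg = cfg or SegmenterConfig()
    bright = bright_pixel_map(image, cfg)
    min_area = int(cfg.min_background_area_frac * image.height * image.width)
    background = _border_connected(bright, min_area)
    tissue = ~background
    tissue = _pad_closing(tissue, cfg.close_radius_px)
    tissue = ndimage.binary_fill_holes(tissue)
    return BinaryMask(tissue, "tissue")


def segment_classical(image: FieldImage, cfg: SegmenterConfig | None = None) -> BinaryMask:
    """Classical reference fat segmenter.

    Pipeline: bright-pixel candidates -> border-background removal (when
    enabled) -> morphological opening -> hole filling -> 8-connected
    labeling -> area and circularity filters -> union of retained
    components.  An image with no candidates yields an all-zero mask.
    """
    cfg = cfg or SegmenterConfig()
    bright = bright_pixel_map(image, cfg)
    if cfg.remove_border_background:
        min_area = int(cfg.min_background_area_frac * image.height * image.width)
        bright &= ~_border_connected(bright, min_area)
    candidates = _pad_opening(bright, cfg.open_radius_px)
    candidates = ndimage.binary_fill_holes(candidates)
    labels, n = ndimage.label(candidates, structure=EIGHT_CONNECTED)
    if n == 0:
        return BinaryMask(np.zeros(image.shape, dtype=bool), "fat")
    areas, _perims, circ = component_metrics(labels, n)
    keep = (areas >= cfg.area_min_px) & (areas <= cfg.area_max_px) & (circ >= cfg.tau_C)
    keep[0] = False
    return BinaryMask(keep[labels], "fat")


def classical_backend(cfg: SegmenterConfig | None = None, per_tile: bool = False) -> Backend:
    """Bind a config into a backend callable for :func:`segment_tiles`.

    ``per_tile=True`` disables border-background removal: tile borders are
    almost never image borders, and the field-level tissue mask (intersected
    with the stitched result downstream) is what excludes background there.
    """
    cfg = cfg or SegmenterConfig()
    if per_tile:
        cfg = replace(cfg, remove_border_background=False)

    def backend(image: FieldImage) -> BinaryMask:
        return segment_classical(image, cfg)

    return backend


def segment_tiles(
    grid: TileGrid,
    tiles: Sequence[FieldImage | np.ndarray],
    backend: Backend | None = None,
    cfg: SegmenterConfig | None = None,
) -> list[BinaryMask]:
    """Run a segmentation backend independently on each tile.

    Any callable honoring the contract (image -> binary mask of the same
    shape) is accepted; output masks are validated and a contract violation
    names the offending tile.
    """
    if len(tiles) != grid.n_tiles:
        raise ContractError(f"expected {grid.n_tiles} tiles, got {len(tiles)}")
    backend = backend or classical_backend(cfg, per_tile=True)
    out: list[BinaryMask] = []
    for i, tile in enumerate(tiles):
        if not isinstance(tile, FieldImage):
            tile = FieldImage(np.asarray(tile), source_id=f"tile-{i}")
        result = backend(tile)
        vals = result.values if isinstance(result, BinaryMask) else np.asarray(result)
        if vals.shape != tile.shape:
            raise ContractError(
                f"backend violated the contract on tile {i}: mask shape {vals.shape} "
                f"!= tile shape {tile.shape}"
            )
        if vals.dtype != bool and not np.all(np.isin(np.unique(vals), (0, 1))):
            raise ContractError(f"backend violated the contract on tile {i}: non-binary output")
        out.append(BinaryMask(vals.astype(bool), "fat"))
    return out
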