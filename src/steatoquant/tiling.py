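"""Decompose an image into square tiles and stitch per-tile masks back losslessly.

Two edge policies are offered.  ``drop_partial`` analyses only tiles that lie
fully inside the source (the border remainder is not analysed at all);
``pad_reflect`` mirror-pads the bottom/right edges so the tile union covers
every source pixel exactly once, with padded pixels flagged so downstream
quantification can exclude them.  Tile order is row-major and stable.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import TilingError
from .types import BinaryMask, FieldImage

POLICIES = ("drop_partial", "pad_reflect")
DEFAULT_TILE_SIZE = 256


@dataclass(frozen=True)
class Tile:
    row: int
    col: int
    y0: int
    x0: int


@dataclass(frozen=True)
class TileGrid:
    """Geometry of a tile decomposition (no pixel data).

    Under ``pad_reflect``, tile windows index into the padded canvas of
    shape ``(padded_height, padded_width)``; under ``drop_partial`` they
    index directly into the source.
    """

    tile_size: int
    policy: str
    source_height: int
    source_width: int
    tiles: tuple[Tile, ...]

    @property
    def n_rows(self) -> int:
        return max(t.row for t in self.tiles) + 1 if self.tiles else 0

    @property
    def n_cols(self) -> int:
        return max(t.col for t in self.tiles) + 1 if self.tiles else 0

    @property
    def n_tiles(self) -> int:
        return len(self.tiles)

    @property
    def padded_height(self) -> int:
        if self.policy == "drop_partial":
            return self.source_height
        return self.n_rows * self.tile_size

    @property
    def padded_width(self) -> int:
        if self.policy == "drop_partial":
            return self.source_width
        return self.n_cols * self.tile_size

    def padded_pixel_count(self) -> int:
        """Number of flagged (mirror-padded) pixels across all tiles."""
        if self.policy == "drop_partial":
            return 0
        return self.padded_height * self.padded_width - self.source_height * self.source_width

    def valid_mask(self, tile: Tile) -> np.ndarray:
        """Boolean tile-shaped mask, True where the tile pixel maps to a source pixel."""
        s = self.tile_size
        valid = np.zeros((s, s), dtype=bool)
        y_lim = min(s, self.source_height - tile.y0)
        x_lim = min(s, self.source_width - tile.x0)
        if y_lim > 0 and x_lim > 0:
            valid[:y_lim, :x_lim] = True
        return valid

    def coverage_mask(self) -> np.ndarray:
        """Boolean source-shaped mask, True where some (non-padded) tile pixel lands."""
        cov = np.zeros((self.source_height, self.source_width), dtype=bool)
        s = self.tile_size
        for t in self.tiles:
            cov[t.y0 : min(t.y0 + s, self.source_height), t.x0 : min(t.x0 + s, self.source_width)] = True
        return cov

    def extract(self, array: np.ndarray | FieldImage | BinaryMask) -> list[np.ndarray]:
        """Slice the source array into per-tile arrays (row-major order)."""
        if isinstance(array, FieldImage):
            array = array.pixels
        elif isinstance(array, BinaryMask):
            array = array.values
        array = np.asarray(array)
        if array.shape[:2] != (self.source_height, self.source_width):
            raise TilingError(
                f"array shape {array.shape[:2]} does not match grid source "
                f"({self.source_height}, {self.source_width})"
            )
        s = self.tile_size
        if self.policy == "pad_reflect":
            pad = [(0, self.padded_height - self.source_height), (0, self.padded_width - self.source_width)]
            pad += [(0, 0)] * (array.ndim - 2)
            array = np.pad(array, pad, mode="symmetric")
        return [array[t.y0 : t.y0 + s, t.x0 : t.x0 + s] for t in self.tiles]

    def to_json(self) -> dict:
        return {
            "tile_size": self.tile_size,
            "policy": self.policy,
            "source_height": self.source_height,
            "source_width": self.source_width,
            "tiles": [[t.row, t.col, t.y0, t.x0] for t in self.tiles],
        }


def tile_image(
    image: FieldImage | np.ndarray,
    tile_size: int = DEFAULT_TILE_SIZE,
    policy: str = "drop_partial",
) -> TileGrid:
    """Build the tile decomposition of an image (geometry only).

    Raises :class:`TilingError` when the image is smaller than one tile
    under ``drop_partial`` (use ``pad_reflect`` for such inputs).
    """
    if isinstance(image, FieldImage):
        h, w = image.shape
    else:
        arr = np.asarray(image)
        h, w = arr.shape[:2]
    if tile_size < 8:
        raise TilingError("tile_size must be >= 8")
    if policy not in POLICIES:
        raise TilingError(f"policy must be one of {POLICIES}, got {policy!r}")
    if policy == "drop_partial":
        n_rows, n_cols = h // tile_size, w // tile_size
        if n_rows == 0 or n_cols == 0:
            raise TilingError(
                f"image ({h}x{w}) is smaller than tile_size {tile_size} under "
                "drop_partial; use policy='pad_reflect'"
            )
    else:
        n_rows, n_cols = math.ceil(h / tile_size), math.ceil(w / tile_size)
    tiles = tuple(
        Tile(row=r, col=c, y0=r * tile_size, x0=c * tile_size)
        for r in range(n_rows)
        for c in range(n_cols)
    )
    return TileGrid(tile_size=tile_size, policy=policy, source_height=h, source_width=w, tiles=tiles)


def stitch_masks(grid: TileGrid, tile_masks: Sequence[BinaryMask | np.ndarray], semantics: str = "fat") -> BinaryMask:
    """Reassemble per-tile masks into one source-shaped mask, discarding padded pixels."""
    if len(tile_masks) != grid.n_tiles:
        raise TilingError(f"expected {grid.n_tiles} tile masks, got {len(tile_masks)}")
    s = grid.tile_size
    canvas = np.zeros((grid.padded_height, grid.padded_width), dtype=bool)
    for i, (tile, mask) in enumerate(zip(grid.tiles, tile_masks)):
        vals = mask.values if isinstance(mask, BinaryMask) else np.asarray(mask)
        if vals.shape != (s, s):
            raise TilingError(
                f"tile {i} (row {tile.row}, col {tile.col}): mask shape {vals.shape} "
                f"!= ({s}, {s})"
            )
        if vals.dtype != bool:
            uniq = np.unique(vals)
            if not np.all(np.isin(uniq, (0, 1))):
                raise TilingError(f"tile {i}: mask is not binary")
            vals = vals.astype(bool)
        canvas[tile.y0 : tile.y0 + s, tile.x0 : tile.x0 + s] = vals
    return BinaryMask(canvas[: grid.source_height, : grid.source_width], semantics)
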