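"""Core containers: field images and binary masks.

Conventions used throughout the package:

* coordinates are 0-based ``(row, col)`` with the origin at the top-left;
* window intervals are half-open;
* a mask value of 1/True means "member of the class named by ``semantics``".
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError

MASK_SEMANTICS = ("fat", "tissue")


@dataclass(frozen=True, eq=False)
class FieldImage:
    """One RGB microscope-field capture (the device's unit of acquisition).

    Parameters
    ----------
    pixels
        ``(H, W, 3)`` uint8 array, 8 bits per channel.
    pixel_size_um
        Microns per pixel, if the optical calibration is known.
    source_id
        Free-text provenance tag (file path, generator seed, crop window).
    """

    pixels: np.ndarray
    pixel_size_um: float | None = None
    source_id: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ContractError(
                f"FieldImage needs an (H, W, 3) array, got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ContractError("FieldImage dimensions must be >= 1")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ContractError("pixel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise ContractError("pixel_size_um must be positive")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def luminance(self) -> np.ndarray:
        """Per-pixel luminance L = mean(R, G, B) / 255, in [0, 1]."""
        return self.pixels.mean(axis=2) / 255.0

    def saturation(self) -> np.ndarray:
        """Per-pixel saturation S = (max - min) / max, with S = 0 where max = 0."""
        px = self.pixels.astype(np.float64)
        mx = px.max(axis=2)
        mn = px.min(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            sat = np.where(mx > 0, (mx - mn) / np.where(mx > 0, mx, 1.0), 0.0)
        return sat


@dataclass(frozen=True, eq=False)
class BinaryMask:
    """Per-pixel binary labels on the same grid as a source image.

    ``semantics`` states what a 1 means: ``"fat"`` (steatosis present) or
    ``"tissue"`` (stained tissue as opposed to empty slide background).
    """

    values: np.ndarray
    semantics: str = "fat"

    def __post_init__(self):
        vals = np.asarray(self.values)
        if vals.ndim != 2:
            raise ContractError(f"BinaryMask needs a 2-D array, got shape {vals.shape}")
        if vals.dtype != bool:
            uniq = np.unique(vals)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ContractError("BinaryMask values must be strictly binary")
            vals = vals.astype(bool)
        object.__setattr__(self, "values", vals)
        if self.semantics not in MASK_SEMANTICS:
            raise ContractError(
                f"semantics must be one of {MASK_SEMANTICS}, got {self.semantics!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def count(self) -> int:
        """Number of 1-pixels."""
        return int(np.count_nonzero(self.values))

    def is_subset_of(self, other: "BinaryMask") -> bool:
        return not np.any(self.values & ~other.values)
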