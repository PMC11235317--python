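"""Shared fixtures and tiny oracle helpers for the test suite."""
from __future__ import annotations

import numpy as np
import pytest

import steatoquant as sq

PINK = (200, 120, 160)
BRIGHT = (242, 240, 244)


def pink_image(h: int, w: int, rgb=PINK) -> np.ndarray:
    """Uniform tissue-coloured RGB array."""
    arr = np.empty((h, w, 3), dtype=np.uint8)
    arr[...] = rgb
    return arr


def white_image(h: int, w: int) -> np.ndarray:
    return pink_image(h, w, rgb=(245, 245, 245))


def paint_disc(arr: np.ndarray, cy: float, cx: float, r: float, rgb=BRIGHT) -> np.ndarray:
    """Paint a bright disc; returns the boolean footprint that was painted."""
    h, w = arr.shape[:2]
    yy, xx = np.ogrid[:h, :w]
    disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
    arr[disc] = rgb
    return disc


def brute_force_fraction(fat: np.ndarray, tissue: np.ndarray) -> tuple[int, int]:
    """Independent double-loop pixel count (the oracle for percent_steatosis)."""
    fat_px = 0
    tissue_px = 0
    for i in range(fat.shape[0]):
        for j in range(fat.shape[1]):
            if tissue[i, j]:
                tissue_px += 1
            if fat[i, j]:
                fat_px += 1
    return fat_px, tissue_px


def iou(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.count_nonzero(a & b)
    union = np.count_nonzero(a | b)
    return inter / union if union else 1.0


@pytest.fixture(scope="session")
def default_cfg() -> sq.RunConfig:
    return sq.RunConfig()


@pytest.fixture(scope="session")
def small_field():
    """One 256x256 synthetic field (margin, moderate steatosis) with its truth."""
    spec = sq.SyntheticSlideSpec(256, 256, target_fat_fraction=0.20, seed=11)
    return sq.generate_field(spec)
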