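"""Seeded synthetic H&E-like liver fields and whole-slide mosaics with exact ground truth.

The generator emulates the image regime a point-of-care steatosis scanner
consumes: pink-textured frozen-section tissue, bright near-circular fat
vacuoles whose diameters follow one continuous lognormal distribution,
bright empty-slide background at the borders, and bright elongated tear
artifacts.  Every output comes with exact per-pixel fat and tissue masks so
the downstream segmenter can be scored against known truth.

Spatial heterogeneity is modelled as a Thomas-style cluster process: with
probability h/(1+h) a vacuole centre is drawn as a Gaussian offset from one
of a few seeded cluster centres (spread shrinking as heterogeneity h grows),
otherwise uniformly.  h = 0 reduces to a uniform (binomial) point process.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import ContractError, FatFractionError
from .types import BinaryMask, FieldImage

# Rendering palette.  The colours are a declared stand-in (no colour
# calibration exists for real frozen sections here); they are chosen so that
# the classical segmenter's luminance/saturation thresholds are meaningful,
# and every value is overridable through the spec.
TISSUE_RGB = (200.0, 120.0, 160.0)
TISSUE_TEXTURE_AMPLITUDE = 15.0  # per-pixel, per-channel uniform jitter
BRIGHT_BASE_RANGE = (239.0, 247.0)  # vacuole / background / tear brightness
BRIGHT_CHANNEL_SPREAD = 4.0  # +- per-channel offset => max spread 8
PIXEL_NOISE_SD = 5.0

DIAMETER_MIN_PX = 4.0
DIAMETER_MAX_PX = 120.0


@dataclass(frozen=True)
class SyntheticSlideSpec:
    """Parameters of one synthetic field or slide mosaic.

    ``target_fat_fraction`` is fat pixels over tissue pixels (fat counts as
    tissue).  ``heterogeneity`` = 0 gives spatially uniform vacuole
    placement; larger values give patchier clustering.  Identical spec +
    seed gives byte-identical output.
    """

    width_px: int
    height_px: int
    target_fat_fraction: float = 0.25
    vacuole_diameter_log_mean: float = math.log(12.0)
    vacuole_diameter_log_sd: float = 0.5
    heterogeneity: float = 0.0
    tear_count: int = 0
    background_margin_px: int = 16
    seed: int = 0
    # Placement controls.  The attempt cap bounds runtime.  Overlapping
    # vacuoles merge (union) in the ground truth, but merging is capped:
    # a new vacuole may overlap existing fat by at most max_overlap_frac of
    # its own area, and a merged cluster may contain at most
    # max_cluster_vacuoles vacuoles, so merged profiles stay compact and
    # near-circular (unbounded chains would be indistinguishable from
    # elongated tear artifacts, which real vacuoles are not).
    # max_overlap_frac = 0 enforces fully separated vacuoles (no
    # 8-adjacency), keeping ground-truth component counts exact.
    max_attempts: int = 10_000
    max_overlap_frac: float = 0.25
    max_cluster_vacuoles: int = 4

    def __post_init__(self):
        if self.width_px < 1 or self.height_px < 1:
            raise ContractError("image dimensions must be positive")
        if not (0.0 <= self.target_fat_fraction <= 0.9):
            raise ContractError("target_fat_fraction must lie in [0, 0.9]")
        if self.vacuole_diameter_log_sd < 0:
            raise ContractError("vacuole_diameter_log_sd must be >= 0")
        if self.heterogeneity < 0:
            raise ContractError("heterogeneity must be >= 0")
        if self.tear_count < 0:
            raise ContractError("tear_count must be >= 0")
        if self.background_margin_px < 0:
            raise ContractError("background_margin_px must be >= 0")
        if 2 * self.background_margin_px >= min(self.width_px, self.height_px):
            raise ContractError("background margin consumes the whole image")
        if self.max_attempts < 1:
            raise ContractError("max_attempts must be >= 1")
        if not (0.0 <= self.max_overlap_frac < 1.0):
            raise ContractError("max_overlap_frac must lie in [0, 1)")
        if self.max_cluster_vacuoles < 1:
            raise ContractError("max_cluster_vacuoles must be >= 1")


@dataclass(frozen=True)
class VacuoleRecord:
    """Ground-truth record of one placed vacuole."""

    centroid: tuple[float, float]  # (row, col)
    diameter_px: float


@dataclass(frozen=True, eq=False)
class GroundTruth:
    """Exact per-pixel truth for one generated image.

    Invariants: ``fat_mask`` is a subset of ``tissue_mask`` and
    ``achieved_fat_fraction`` equals the exact pixel-count ratio of the two.
    """

    fat_mask: BinaryMask
    tissue_mask: BinaryMask
    vacuole_records: tuple[VacuoleRecord, ...]
    achieved_fat_fraction: float

    def __post_init__(self):
        if self.fat_mask.shape != self.tissue_mask.shape:
            raise ContractError("fat and tissue masks must share a shape")
        if not self.fat_mask.is_subset_of(self.tissue_mask):
            raise ContractError("fat_mask must be a subset of tissue_mask")


def _draw_tear(rng: np.random.Generator, shape: tuple[int, int], interior: np.ndarray) -> np.ndarray:
    """Render one bright elongated tear as a thick, slightly wandering polyline.

    Width is kept well under length/4 so the tear's circularity stays far
    below any plausible vacuole's.
    """
    h, w = shape
    length = rng.uniform(0.15, 0.30) * min(h, w)
    width = rng.uniform(3.0, max(3.5, min(8.0, length / 10.0)))
    theta = rng.uniform(0.0, 2.0 * math.pi)
    y = rng.uniform(0.2 * h, 0.8 * h)
    x = rng.uniform(0.2 * w, 0.8 * w)
    n_steps = max(2, int(length))
    ys = np.empty(n_steps)
    xs = np.empty(n_steps)
    wander = rng.normal(0.0, 0.03, size=n_steps)
    for i in range(n_steps):
        ys[i], xs[i] = y, x
        theta += wander[i]
        y += math.sin(theta)
        x += math.cos(theta)
    path = np.zeros(shape, dtype=bool)
    iy = np.clip(np.round(ys).astype(int), 0, h - 1)
    ix = np.clip(np.round(xs).astype(int), 0, w - 1)
    path[iy, ix] = True
    radius = max(1, int(round(width / 2)))
    yy, xx = np.ogrid[-radius : radius + 1, -radius : radius + 1]
    footprint = (yy * yy + xx * xx) <= radius * radius
    tear = ndimage.binary_dilation(path, structure=footprint)
    return tear & interior


def _cluster_state(rng: np.random.Generator, spec: SyntheticSlideSpec):
    """Seeded cluster centres and spread for heterogeneous placement."""
    if spec.heterogeneity <= 0:
        return None
    h, w = spec.height_px, spec.width_px
    n_clusters = max(2, int(round((h * w) / (768.0 * 768.0))) + 1)
    centers = np.column_stack(
        [rng.uniform(0.15 * h, 0.85 * h, n_clusters), rng.uniform(0.15 * w, 0.85 * w, n_clusters)]
    )
    # Patches must be macroscopic (field-scale) to reproduce the patchy
    # steatosis regime: heterogeneity mostly controls the share of vacuoles
    # drawn from patches, with patch spread shrinking slowly as h grows.
    sigma = min(h, w) / (3.0 * (1.0 + spec.heterogeneity) ** 0.25)
    p_cluster = spec.heterogeneity / (1.0 + spec.heterogeneity)
    return centers, sigma, p_cluster


def _place_vacuoles(
    rng: np.random.Generator,
    spec: SyntheticSlideSpec,
    tissue: np.ndarray,
) -> tuple[np.ndarray, list[VacuoleRecord]]:
    """Rejection-sample vacuole discs until the fat fraction lands in the target band.

    A placement is rejected when the disc (with a one-pixel clearance ring)
    leaves the tissue, touches a tear or the background, overlaps existing
    fat beyond ``max_overlap_frac`` of its own area, or would overshoot the
    target band.  Raises :class:`FatFractionError` at the attempt cap.
    """
    h, w = tissue.shape
    fat = np.zeros_like(tissue)
    records: list[VacuoleRecord] = []
    tissue_px = int(tissue.sum())
    if tissue_px == 0 or spec.target_fat_fraction == 0.0:
        return fat, records
    target_px = spec.target_fat_fraction * tissue_px
    tol_px = 0.005 * tissue_px
    clusters = _cluster_state(rng, spec)

    # Union-find over placed vacuoles tracks merged-cluster sizes; `owner`
    # maps each fat pixel to the id of the vacuole that painted it.
    owner = np.zeros((h, w), dtype=np.int32)
    parent: list[int] = [0]
    member_count: list[int] = [0]

    def find(i: int) -> int:
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    fat_px = 0
    attempts = 0
    separate = spec.max_overlap_frac <= 0.0

    # Proposal free-list (uniform placement only): candidate centres are
    # restricted to pixels where even the smallest disc could still fit.
    # Proposals stay uniform over every diameter's feasible set (the
    # feasible set for any d is a subset of the free-list), so this only
    # removes guaranteed rejections; it is refreshed as the field fills up.
    freelist: np.ndarray | None = None
    rejection_streak = 0
    min_clear = int(math.ceil(DIAMETER_MIN_PX / 2.0 + 2.0))

    def refresh_freelist() -> np.ndarray:
        blocked_r = min_clear
        yy, xx = np.ogrid[-blocked_r : blocked_r + 1, -blocked_r : blocked_r + 1]
        footprint = (yy * yy + xx * xx) <= blocked_r * blocked_r
        blocked = ndimage.binary_dilation(fat | ~tissue, structure=footprint)
        return np.flatnonzero(~blocked)

    while fat_px < target_px - tol_px:
        if attempts >= spec.max_attempts:
            achieved = fat_px / tissue_px
            raise FatFractionError(
                f"could not reach fat fraction {spec.target_fat_fraction:.4f} within "
                f"{spec.max_attempts} placements; achieved {achieved:.4f}",
                achieved=achieved,
            )
        attempts += 1
        d = math.exp(rng.normal(spec.vacuole_diameter_log_mean, spec.vacuole_diameter_log_sd))
        if not (DIAMETER_MIN_PX <= d <= DIAMETER_MAX_PX):
            continue
        r = d / 2.0
        if clusters is None:
            if freelist is None or rejection_streak >= 400:
                freelist = refresh_freelist()
                rejection_streak = 0
                if freelist.size == 0:
                    achieved = fat_px / tissue_px
                    raise FatFractionError(
                        f"field saturated at fat fraction {achieved:.4f}; target "
                        f"{spec.target_fat_fraction:.4f} is unreachable",
                        achieved=achieved,
                    )
            pos = int(freelist[rng.integers(freelist.size)])
            cy = pos // w + rng.uniform(-0.5, 0.5)
            cx = pos % w + rng.uniform(-0.5, 0.5)
        else:
            centers, sigma, p_cluster = clusters
            if rng.random() < p_cluster:
                base = centers[rng.integers(len(centers))]
                cy = base[0] + rng.normal(0.0, sigma)
                cx = base[1] + rng.normal(0.0, sigma)
            else:
                cy = rng.uniform(0.0, h)
                cx = rng.uniform(0.0, w)
        r_clear = r + 1.5  # clearance ring: keeps 8-connectivity separation from non-tissue
        y0, y1 = int(math.floor(cy - r_clear)), int(math.ceil(cy + r_clear)) + 1
        x0, x1 = int(math.floor(cx - r_clear)), int(math.ceil(cx + r_clear)) + 1
        if y0 < 0 or x0 < 0 or y1 > h or x1 > w:
            rejection_streak += 1
            continue
        yy = np.arange(y0, y1, dtype=np.float64)[:, None] - cy
        xx = np.arange(x0, x1, dtype=np.float64)[None, :] - cx
        dist2 = yy * yy + xx * xx
        disc = dist2 <= r * r
        clear = dist2 <= r_clear * r_clear
        region_tissue = tissue[y0:y1, x0:x1]
        if np.any(clear & ~region_tissue):
            rejection_streak += 1
            continue
        region_fat = fat[y0:y1, x0:x1]
        disc_area = int(disc.sum())
        if disc_area == 0:
            rejection_streak += 1
            continue
        region_owner = owner[y0:y1, x0:x1]
        touched = np.unique(region_owner[clear])
        touched = touched[touched > 0]
        roots = {find(int(t)) for t in touched}
        if separate:
            if roots:
                rejection_streak += 1
                continue
            overlap = 0
        else:
            overlap = int(np.count_nonzero(disc & region_fat))
            if overlap > spec.max_overlap_frac * disc_area:
                rejection_streak += 1
                continue
            if 1 + sum(member_count[rt] for rt in roots) > spec.max_cluster_vacuoles:
                rejection_streak += 1
                continue
        new_px = disc_area - overlap
        if fat_px + new_px > target_px + tol_px:
            rejection_streak += 1
            continue
        rejection_streak = 0
        new_id = len(parent)
        parent.append(new_id)
        member_count.append(1 + sum(member_count[rt] for rt in roots))
        for rt in roots:
            parent[rt] = new_id
        paint = disc & ~region_fat
        region_owner[paint] = new_id
        region_fat |= disc
        fat_px += new_px
        records.append(VacuoleRecord(centroid=(cy, cx), diameter_px=d))
    return fat, records


def _render(rng: np.random.Generator, tissue: np.ndarray, fat: np.ndarray) -> np.ndarray:
    """Render the RGB image from the layout masks.

    Bright pixels (fat, background, tears) share one palette: per-pixel base
    brightness in ``BRIGHT_BASE_RANGE`` with a small per-channel spread.
    Tissue pixels get the pink base colour with per-pixel texture.  Gaussian
    read noise is added everywhere.
    """
    h, w = tissue.shape
    img = np.empty((h, w, 3), dtype=np.float32)
    texture = rng.random((h, w, 3), dtype=np.float32)
    texture *= 2.0 * TISSUE_TEXTURE_AMPLITUDE
    texture -= TISSUE_TEXTURE_AMPLITUDE
    for c, mu in enumerate(TISSUE_RGB):
        img[..., c] = mu + texture[..., c]
    bright = fat | ~tissue
    lo, hi = BRIGHT_BASE_RANGE
    base = lo + (hi - lo) * rng.random((h, w), dtype=np.float32)
    spread = rng.random((h, w, 3), dtype=np.float32)
    spread *= 2.0 * BRIGHT_CHANNEL_SPREAD
    spread -= BRIGHT_CHANNEL_SPREAD
    bright_rgb = base[..., None] + spread
    img[bright] = bright_rgb[bright]
    noise = rng.standard_normal((h, w, 3), dtype=np.float32)
    img += PIXEL_NOISE_SD * noise
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def _generate(spec: SyntheticSlideSpec, kind: str) -> tuple[FieldImage, GroundTruth]:
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    tissue = np.ones((h, w), dtype=bool)
    m = spec.background_margin_px
    if m > 0:
        tissue[:m, :] = False
        tissue[-m:, :] = False
        tissue[:, :m] = False
        tissue[:, -m:] = False
    interior = tissue.copy()
    for _ in range(spec.tear_count):
        tissue &= ~_draw_tear(rng, (h, w), interior)
    fat, records = _place_vacuoles(rng, spec, tissue)
    pixels = _render(rng, tissue, fat)
    tissue_px = int(tissue.sum())
    achieved = float(fat.sum()) / tissue_px if tissue_px else 0.0
    truth = GroundTruth(
        fat_mask=BinaryMask(fat, "fat"),
        tissue_mask=BinaryMask(tissue, "tissue"),
        vacuole_records=tuple(records),
        achieved_fat_fraction=achieved,
    )
    image = FieldImage(pixels, source_id=f"synthetic-{kind}-seed{spec.seed}")
    return image, truth


def generate_field(spec: SyntheticSlideSpec) -> tuple[FieldImage, GroundTruth]:
    """Generate one synthetic microscope-field image with exact ground truth."""
    return _generate(spec, "field")


def generate_slide(spec: SyntheticSlideSpec) -> tuple[FieldImage, GroundTruth]:
    """Generate a whole-slide analog mosaic.

    Same contract as :func:`generate_field` at mosaic scale; heterogeneity
    (clustered vacuole placement) is typically of interest here, since field
    sampling only disagrees with the whole-slide score on patchy slides.
    """
    return _generate(spec, "slide")


def spec_with_seed(spec: SyntheticSlideSpec, seed: int) -> SyntheticSlideSpec:
    """Convenience: the same spec under a different seed."""
    return replace(spec, seed=int(seed))
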