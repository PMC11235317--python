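"""Device-vs-whole-slide agreement experiment on synthetic slides.

A point-of-care device scores a slide from a handful of microscope-field
captures, while a whole-slide platform scores every pixel.  On slides with
spatially uniform steatosis the two agree closely; on patchy slides the
sampled estimate diverges.  This module reproduces that comparison at desk
scale: generate synthetic slides with known ground truth, score each slide
both ways with the *same* segmentation backend (so sampling is the only
modelled difference), and correlate the two arms.

The patchiness of a slide is summarized by a quadrat-style heterogeneity
index: the coefficient of variation of per-block fat fractions.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig
from .errors import ContractError, SamplingError
from .quantification import quantify_field, quantify_slide
from .synthetic import SyntheticSlideSpec, generate_slide
from .types import BinaryMask, FieldImage

logger = logging.getLogger(__name__)

VACUOLE_MEAN_AREA_PX = 186.0  # lognormal(ln 12, 0.5) diameter -> mean disc area


@dataclass(frozen=True)
class SlideComparison:
    slide_id: int
    wholeslide_fraction: float
    device_fraction: float
    ground_truth_fraction: float
    abs_deviation: float
    heterogeneity_index: float


@dataclass(frozen=True)
class ComparisonResult:
    per_slide: tuple[SlideComparison, ...]
    pearson_r: float
    slope_through_origin: float
    ols_slope: float
    ols_intercept: float
    config: dict

    @property
    def n_slides(self) -> int:
        return len(self.per_slide)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "slide_id": [s.slide_id for s in self.per_slide],
                "wholeslide_fraction": [s.wholeslide_fraction for s in self.per_slide],
                "device_fraction": [s.device_fraction for s in self.per_slide],
                "ground_truth_fraction": [s.ground_truth_fraction for s in self.per_slide],
                "abs_deviation": [s.abs_deviation for s in self.per_slide],
                "heterogeneity_index": [s.heterogeneity_index for s in self.per_slide],
            }
        )

    def to_dict(self) -> dict:
        return {
            "n_slides": self.n_slides,
            "pearson_r": self.pearson_r,
            "slope_through_origin": self.slope_through_origin,
            "ols_slope": self.ols_slope,
            "ols_intercept": self.ols_intercept,
            "config": self.config,
            "per_slide": self.to_dataframe().to_dict(orient="records"),
        }


def sample_fields(
    slide: FieldImage,
    k: int,
    field_h: int,
    field_w: int,
    seed: int,
    allow_overlap: bool = False,
    max_attempts: int = 10_000,
) -> list[tuple[FieldImage, tuple[int, int]]]:
    """Draw k field windows uniformly at random, pairwise non-overlapping.

    Mimics a physician moving the stage to different areas of a slide.
    Rejection sampling with a capped number of attempts; the error on
    failure states how many fields could be placed and the grid capacity.
    """
    if k < 1:
        raise ContractError("k must be >= 1")
    if field_h > slide.height or field_w > slide.width:
        raise ContractError(
            f"field ({field_h}x{field_w}) exceeds slide ({slide.height}x{slide.width})"
        )
    rng = np.random.default_rng(seed)
    placed: list[tuple[int, int]] = []
    attempts = 0
    streak = 0
    best = 0
    while len(placed) < k:
        if attempts >= max_attempts:
            capacity = (slide.height // field_h) * (slide.width // field_w)
            raise SamplingError(
                f"could not place {k} non-overlapping {field_h}x{field_w} fields "
                f"(best {best} placed in {attempts} attempts); "
                f"maximum feasible k is at most {capacity}"
            )
        attempts += 1
        y0 = int(rng.integers(0, slide.height - field_h + 1))
        x0 = int(rng.integers(0, slide.width - field_w + 1))
        if not allow_overlap:
            if any(abs(y0 - py) < field_h and abs(x0 - px) < field_w for py, px in placed):
                streak += 1
                # an unlucky early placement can block the rest; restart
                if streak >= 500:
                    placed.clear()
                    streak = 0
                continue
        placed.append((y0, x0))
        best = max(best, len(placed))
        streak = 0
    fields = []
    for y0, x0 in placed:
        crop = slide.pixels[y0 : y0 + field_h, x0 : x0 + field_w].copy()
        fields.append(
            (
                FieldImage(
                    crop,
                    pixel_size_um=slide.pixel_size_um,
                    source_id=f"{slide.source_id}@({y0},{x0})",
                ),
                (y0, x0),
            )
        )
    return fields


def pearson_r(x, y) -> float:
    """Product-moment correlation; undefined (an error) for constant input."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ContractError("x and y must be 1-D and of equal length")
    if x.size < 3:
        raise ContractError("pearson_r needs at least 3 points")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ContractError("pearson_r is undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def heterogeneity_index(fat: BinaryMask, tissue: BinaryMask, window: int = 256) -> float:
    """Coefficient of variation of per-block fat fractions (quadrat analysis).

    The masks are partitioned into window x window blocks (partial blocks
    dropped); blocks with at least 25% tissue qualify; the index is
    sd/mean (population sd) of the qualifying block fractions, defined as 0
    when the mean is 0.  High values mean patchy steatosis.
    """
    if window < 8:
        raise ContractError("window must be >= 8")
    if fat.shape != tissue.shape:
        raise ContractError("masks must share a shape")
    h, w = fat.shape
    n_rows, n_cols = h // window, w // window
    if n_rows == 0 or n_cols == 0:
        raise ContractError("no complete blocks at this window size")
    fat_blocks = (
        fat.values[: n_rows * window, : n_cols * window]
        .reshape(n_rows, window, n_cols, window)
        .sum(axis=(1, 3))
    )
    tissue_blocks = (
        tissue.values[: n_rows * window, : n_cols * window]
        .reshape(n_rows, window, n_cols, window)
        .sum(axis=(1, 3))
    )
    qualifying = tissue_blocks >= 0.25 * window * window
    if not np.any(qualifying):
        raise ContractError("no blocks with >= 25% tissue at this window size")
    fractions = fat_blocks[qualifying] / tissue_blocks[qualifying]
    mean = fractions.mean()
    if mean == 0:
        return 0.0
    return float(fractions.std(ddof=0) / mean)


def _slide_spec(
    target: float,
    heterogeneity: float,
    seed: int,
    slide_h: int,
    slide_w: int,
) -> SyntheticSlideSpec:
    # scale the placement-attempt cap with mosaic area so dense mosaics stay
    # reachable; targets near the packing limit need many rejected proposals
    max_attempts = max(50_000, 4 * slide_h * slide_w)
    return SyntheticSlideSpec(
        width_px=slide_w,
        height_px=slide_h,
        target_fat_fraction=target,
        heterogeneity=heterogeneity,
        seed=seed,
        max_attempts=max_attempts,
    )


def run_comparison(
    n_slides: int = 33,
    fat_fraction_range: tuple[float, float] = (0.02, 0.60),
    heterogeneity: float = 0.0,
    k: int = 3,
    seed: int = 0,
    config: RunConfig | None = None,
    slide_height: int = 2160,
    slide_width: int = 3240,
    field_height: int | None = None,
    field_width: int | None = None,
    het_window: int | None = None,
) -> ComparisonResult:
    """Scaled device-vs-whole-slide comparison experiment.

    For each slide: draw a target fat fraction uniformly from
    ``fat_fraction_range``, generate a synthetic slide, score the full
    mosaic with ``pad_reflect`` tiling (whole-slide arm), score k sampled
    fields through the stability filter and field averaging (device arm),
    and record ground truth, absolute deviation and heterogeneity index.
    Fully seeded and deterministic.
    """
    if n_slides < 3:
        raise ContractError("n_slides must be >= 3 (correlation needs >= 3 points)")
    lo, hi = fat_fraction_range
    if not (0.0 <= lo <= hi <= 0.9):
        raise ContractError("fat_fraction_range must satisfy 0 <= lo <= hi <= 0.9")
    cfg = config or RunConfig()
    fh = field_height or cfg.field_height
    fw = field_width or cfg.field_width
    if slide_height < 2 * fh or slide_width < 2 * fw:
        raise ContractError("slide dimensions must be at least twice the field dimensions")
    window = het_window or cfg.tile_size
    whole_cfg = cfg.with_updates(tile_policy="pad_reflect")
    device_cfg = cfg
    rng = np.random.default_rng(seed)
    per_slide = []
    for i in range(n_slides):
        target = float(rng.uniform(lo, hi))
        slide_seed = int(rng.integers(2**31))
        sample_seed = int(rng.integers(2**31))
        spec = _slide_spec(target, heterogeneity, slide_seed, slide_height, slide_width)
        slide_img, truth = generate_slide(spec)
        whole = quantify_field(slide_img, whole_cfg)
        fields = [f for f, _ in sample_fields(slide_img, k, fh, fw, seed=sample_seed)]
        device = quantify_slide(fields, device_cfg)
        if not device.valid:
            raise SamplingError(
                f"slide {i}: device estimate invalid ({device.invalid_reason})"
            )
        het = heterogeneity_index(truth.fat_mask, truth.tissue_mask, window)
        per_slide.append(
            SlideComparison(
                slide_id=i,
                wholeslide_fraction=whole.fraction,
                device_fraction=device.slide_fraction,
                ground_truth_fraction=truth.achieved_fat_fraction,
                abs_deviation=abs(device.slide_fraction - whole.fraction),
                heterogeneity_index=het,
            )
        )
        logger.info(
            "slide %d: truth=%.4f wholeslide=%.4f device=%.4f het=%.3f",
            i, truth.achieved_fat_fraction, whole.fraction, device.slide_fraction, het,
        )
    xs = np.array([s.wholeslide_fraction for s in per_slide])
    ys = np.array([s.device_fraction for s in per_slide])
    r = pearson_r(xs, ys)
    slope0 = float((xs * ys).sum() / (xs * xs).sum())
    ols_slope, ols_intercept = (float(v) for v in np.polyfit(xs, ys, 1))
    return ComparisonResult(
        per_slide=tuple(per_slide),
        pearson_r=r,
        slope_through_origin=slope0,
        ols_slope=ols_slope,
        ols_intercept=ols_intercept,
        config={
            "n_slides": n_slides,
            "fat_fraction_range": [lo, hi],
            "heterogeneity": heterogeneity,
            "k": k,
            "seed": seed,
            "slide_height": slide_height,
            "slide_width": slide_width,
            "field_height": fh,
            "field_width": fw,
            "het_window": window,
            "tile_size": cfg.tile_size,
        },
    )


def plot_comparison(result: ComparisonResult, path) -> None:
    """Scatter of device vs whole-slide scores with OLS and through-origin trend lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs = np.array([s.wholeslide_fraction for s in result.per_slide])
    ys = np.array([s.device_fraction for s in result.per_slide])
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(xs, ys, s=25, edgecolor="k", facecolor="none")
    grid = np.linspace(0, max(xs.max(), ys.max()) * 1.05, 50)
    ax.plot(grid, result.slope_through_origin * grid, "-", color="tab:blue",
            label=f"through origin (slope {result.slope_through_origin:.3f})")
    ax.plot(grid, result.ols_slope * grid + result.ols_intercept, "--", color="tab:orange",
            label=f"OLS (r = {result.pearson_r:.4f})")
    ax.set_xlabel("whole-slide steatosis fraction")
    ax.set_ylabel("device (sampled fields) steatosis fraction")
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
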