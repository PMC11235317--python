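"""Assemble JSON-serializable report payloads from pipeline results."""
from __future__ import annotations

from importlib import metadata

from .config import RunConfig
from .quantification import SlideEstimate

SCHEMA_VERSION = 1

try:
    _VERSION = metadata.version("steatoquant")
except metadata.PackageNotFoundError:  # pragma: no cover
    _VERSION = "unknown"


def build_quantify_report(
    estimate: SlideEstimate,
    config: RunConfig,
    seed: int,
    inputs: list[dict] | None = None,
) -> dict:
    """Quantification report: per-field counts plus the slide aggregate.

    Fractions are reported in [0, 1] with an explicit display-percent field
    so percent/fraction confusion cannot arise downstream.
    """
    fields = [
        {
            "source_id": e.source_id,
            "fat_px": e.fat_px,
            "tissue_px": e.tissue_px,
            "fraction": e.fraction,
            "percent": 100.0 * e.fraction,
            "n_tiles": e.n_tiles,
            "per_tile_fractions": e.per_tile_fractions,
        }
        for e in estimate.field_estimates
    ]
    return {
        "schema_version": SCHEMA_VERSION,
        "package": {"name": "steatoquant", "version": _VERSION},
        "seed": seed,
        "config": config.to_dict(),
        "inputs": inputs or [],
        "fields": fields,
        "slide": {
            "slide_fraction": estimate.slide_fraction,
            "percent": None if estimate.slide_fraction is None else 100.0 * estimate.slide_fraction,
            "pooled_fraction": estimate.pooled_fraction,
            "n_fields": estimate.n_fields,
            "rejected_fields": [list(r) for r in estimate.rejected_fields],
            "valid": estimate.valid,
            "invalid_reason": estimate.invalid_reason,
        },
    }


def build_validate_report(result_dict: dict, seed: int) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "package": {"name": "steatoquant", "version": _VERSION},
        "seed": seed,
        "comparison": result_dict,
    }
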