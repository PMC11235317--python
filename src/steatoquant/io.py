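"""Image and report IO.

Images: 8-bit RGB PNG/TIFF in, PNG/TIFF images and single-channel 0/255 PNG
masks out.  Reports: deterministic JSON (sorted keys, floats formatted to 6
significant digits) so identical runs are byte-identical; a JSON-schema for
the quantification report ships with the package, together with a minimal
validator for the schema subset it uses.  Reports never embed input images,
only their paths and SHA-256 hashes.
"""
from __future__ import annotations

import hashlib
import json
import logging
from importlib import resources
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .errors import SchemaError, SteatoquantError
from .types import BinaryMask, FieldImage

logger = logging.getLogger(__name__)

SIGNIFICANT_DIGITS = 6


def read_image(path) -> FieldImage:
    """Read a PNG or TIFF into an 8-bit RGB FieldImage.

    Grayscale inputs are promoted to three identical channels and 16-bit
    inputs rescaled to 8-bit, each with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise SteatoquantError(f"image file not found: {path}")
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        elif suffix == ".png":
            arr = np.asarray(Image.open(path))
        else:
            raise SteatoquantError(f"unsupported image format {suffix!r}: {path}")
    except SteatoquantError:
        raise
    except Exception as exc:
        raise SteatoquantError(f"could not read image {path}: {exc}") from exc
    if arr.ndim == 2:
        logger.warning("%s: grayscale input promoted to RGB", path)
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3:
        raise SteatoquantError(f"unsupported image layout {arr.shape} in {path}")
    if arr.shape[2] == 4:
        arr = arr[..., :3]
    if arr.shape[2] != 3:
        raise SteatoquantError(f"expected 1, 3 or 4 channels, got {arr.shape[2]} in {path}")
    if arr.dtype == np.uint16:
        logger.warning("%s: 16-bit input rescaled to 8-bit", path)
        arr = (arr.astype(np.float64) / 257.0).round().astype(np.uint8)
    elif arr.dtype != np.uint8:
        raise SteatoquantError(f"unsupported pixel dtype {arr.dtype} in {path}")
    return FieldImage(arr, source_id=str(path))


def write_image(image: FieldImage | np.ndarray, path) -> Path:
    """Write an RGB image as PNG or TIFF (by extension)."""
    path = Path(path)
    arr = image.pixels if isinstance(image, FieldImage) else np.asarray(image)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr, mode="RGB").save(path)
    return path


def write_mask(mask: BinaryMask | np.ndarray, path) -> Path:
    """Write a binary mask as a single-channel PNG, 255 = set ("white"), 0 = else."""
    path = Path(path)
    vals = mask.values if isinstance(mask, BinaryMask) else np.asarray(mask).astype(bool)
    Image.fromarray((vals.astype(np.uint8) * 255), mode="L").save(path)
    return path


def sha256_of_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _round_floats(obj):
    """Recursively format floats to 6 significant digits for byte-stable JSON."""
    if isinstance(obj, bool):
        return obj
    if isinstance(obj, float):
        if obj != obj or obj in (float("inf"), float("-inf")):
            return None
        return float(f"{obj:.{SIGNIFICANT_DIGITS}g}")
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj))
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    if isinstance(obj, dict):
        return {str(k): _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    return obj


def write_report(data: dict, path) -> Path:
    """Write a deterministic JSON report (sorted keys, fixed float formatting)."""
    path = Path(path)
    try:
        text = json.dumps(_round_floats(data), sort_keys=True, indent=2)
        path.write_text(text + "\n")
    except OSError as exc:
        raise SteatoquantError(f"could not write report to {path}: {exc}") from exc
    return path


def load_report_schema() -> dict:
    with resources.files("steatoquant.schemas").joinpath("report.schema.json").open() as fh:
        return json.load(fh)


_TYPE_CHECKS = {
    "object": lambda v: isinstance(v, dict),
    "array": lambda v: isinstance(v, list),
    "string": lambda v: isinstance(v, str),
    "number": lambda v: isinstance(v, (int, float)) and not isinstance(v, bool),
    "integer": lambda v: isinstance(v, int) and not isinstance(v, bool),
    "boolean": lambda v: isinstance(v, bool),
    "null": lambda v: v is None,
}


def validate_schema(data, schema: dict, path: str = "$") -> None:
    """Validate ``data`` against the subset of JSON Schema this package ships
    (type / properties / required / items / enum; type may be a list).

    Raises :class:`SchemaError` naming the first offending location.
    """
    types = schema.get("type")
    if types is not None:
        if isinstance(types, str):
            types = [types]
        if not any(_TYPE_CHECKS[t](data) for t in types):
            raise SchemaError(f"{path}: expected type {types}, got {type(data).__name__}")
    if "enum" in schema and data not in schema["enum"]:
        raise SchemaError(f"{path}: value {data!r} not in enum {schema['enum']}")
    if isinstance(data, dict):
        for key in schema.get("required", []):
            if key not in data:
                raise SchemaError(f"{path}: missing required key {key!r}")
        for key, subschema in schema.get("properties", {}).items():
            if key in data:
                validate_schema(data[key], subschema, f"{path}.{key}")
    if isinstance(data, list) and "items" in schema:
        for i, item in enumerate(data):
            validate_schema(item, schema["items"], f"{path}[{i}]")


def validate_report(data: dict) -> None:
    """Validate a quantification report against the shipped schema."""
    validate_schema(data, load_report_schema())
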