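"""Vacuole-level analysis of a fat mask: counting, sizes, macro/micro split.

Vacuoles are 8-connected components of the fat mask.  The size measure is
the equivalent-circle diameter 2*sqrt(area/pi) (robust for near-circular
vacuoles); when the pixel size is known, diameters are also reported in
microns.  The macro/micro characterization is exploratory: there is no
asserted clinical diameter cut, so the threshold is an explicit parameter.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ContractError
from .segmentation import EIGHT_CONNECTED, component_metrics
from .types import BinaryMask


@dataclass(frozen=True)
class Vacuole:
    id: int
    area_px: int
    equivalent_diameter_px: float
    centroid: tuple[float, float]  # (row, col)
    circularity: float
    diameter_um: float | None = None


@dataclass(frozen=True)
class VacuoleSet:
    vacuoles: tuple[Vacuole, ...]
    total_fat_px: int
    source_id: str = ""

    def __post_init__(self):
        if sum(v.area_px for v in self.vacuoles) != self.total_fat_px:
            raise ContractError("vacuole areas must sum to the fat pixel count")

    @property
    def n(self) -> int:
        return len(self.vacuoles)

    def diameters(self, prefer_um: bool = True) -> np.ndarray:
        """Equivalent diameters, in um when available (all or none), else px."""
        if prefer_um and self.vacuoles and all(v.diameter_um is not None for v in self.vacuoles):
            return np.array([v.diameter_um for v in self.vacuoles])
        return np.array([v.equivalent_diameter_px for v in self.vacuoles])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [v.id for v in self.vacuoles],
                "area_px": [v.area_px for v in self.vacuoles],
                "equivalent_diameter_px": [v.equivalent_diameter_px for v in self.vacuoles],
                "diameter_um": [v.diameter_um for v in self.vacuoles],
                "circularity": [v.circularity for v in self.vacuoles],
                "centroid_row": [v.centroid[0] for v in self.vacuoles],
                "centroid_col": [v.centroid[1] for v in self.vacuoles],
            }
        )


@dataclass(frozen=True)
class SizeDistribution:
    bin_edges: tuple[float, ...]
    counts: tuple[int, ...]
    n: int
    mean: float | None
    median: float | None
    sd: float | None
    units: str  # "um" or "px"


@dataclass(frozen=True)
class MacroMicroSplit:
    threshold: float
    units: str
    macro_count: int
    micro_count: int
    macro_area_px: int
    micro_area_px: int
    macro_area_fraction: float
    micro_area_fraction: float


def label_vacuoles(fat: BinaryMask | np.ndarray, pixel_size_um: float | None = None) -> VacuoleSet:
    """8-connected component labeling of a fat mask into a VacuoleSet.

    Ids are assigned in deterministic row-major order of each component's
    topmost-leftmost pixel.  An empty mask yields an empty set.
    """
    vals = fat.values if isinstance(fat, BinaryMask) else np.asarray(fat).astype(bool)
    labels, n = ndimage.label(vals, structure=EIGHT_CONNECTED)
    if n == 0:
        return VacuoleSet(vacuoles=(), total_fat_px=0)
    # order components by first-encountered (row-major) pixel
    first_idx = np.full(n + 1, labels.size, dtype=np.int64)
    np.minimum.at(first_idx, labels.ravel(), np.arange(labels.size))
    order = np.argsort(first_idx[1:], kind="stable")  # label-1 indices in id order
    areas, _perims, circ = component_metrics(labels, n)
    centroids = ndimage.center_of_mass(vals, labels, index=np.arange(1, n + 1))
    vacuoles = []
    for new_id, lab_idx in enumerate(order, start=1):
        lab = lab_idx + 1
        area = int(areas[lab])
        eq_d = 2.0 * math.sqrt(area / math.pi)
        vacuoles.append(
            Vacuole(
                id=new_id,
                area_px=area,
                equivalent_diameter_px=eq_d,
                centroid=(float(centroids[lab_idx][0]), float(centroids[lab_idx][1])),
                circularity=float(circ[lab]),
                diameter_um=eq_d * pixel_size_um if pixel_size_um else None,
            )
        )
    return VacuoleSet(vacuoles=tuple(vacuoles), total_fat_px=int(np.count_nonzero(vals)))


def size_distribution(vs: VacuoleSet, bin_edges) -> SizeDistribution:
    """Histogram + summary (n, mean, median, sd) of equivalent diameters.

    Diameters outside the given edges are counted in the first/last bin
    (values are clipped) so that the counts always sum to n.
    """
    edges = np.asarray(bin_edges, dtype=np.float64)
    if edges.ndim != 1 or edges.size < 2:
        raise ContractError("bin_edges must be a 1-D sequence of length >= 2")
    if np.any(edges < 0) or np.any(np.diff(edges) <= 0):
        raise ContractError("bin_edges must be non-negative and strictly increasing")
    units = "um" if (vs.vacuoles and all(v.diameter_um is not None for v in vs.vacuoles)) else "px"
    if vs.n == 0:
        return SizeDistribution(
            bin_edges=tuple(edges.tolist()),
            counts=tuple([0] * (edges.size - 1)),
            n=0, mean=None, median=None, sd=None, units=units,
        )
    diam = vs.diameters()
    clipped = np.clip(diam, edges[0], edges[-1])
    counts, _ = np.histogram(clipped, bins=edges)
    return SizeDistribution(
        bin_edges=tuple(edges.tolist()),
        counts=tuple(int(c) for c in counts),
        n=vs.n,
        mean=float(diam.mean()),
        median=float(np.median(diam)),
        sd=float(diam.std(ddof=1)) if vs.n > 1 else 0.0,
        units=units,
    )


def classify_macro_micro(vs: VacuoleSet, diameter_threshold: float) -> MacroMicroSplit:
    """Split vacuoles at an equivalent-diameter threshold (>= threshold is macro).

    Fractions are each class's pixel area over the total fat area; the two
    areas always sum to the fat pixel count.
    """
    if diameter_threshold <= 0:
        raise ContractError("diameter threshold must be > 0")
    units = "um" if (vs.vacuoles and all(v.diameter_um is not None for v in vs.vacuoles)) else "px"
    if vs.n == 0:
        return MacroMicroSplit(diameter_threshold, units, 0, 0, 0, 0, 0.0, 0.0)
    diam = vs.diameters()
    areas = np.array([v.area_px for v in vs.vacuoles])
    macro = diam >= diameter_threshold
    macro_area = int(areas[macro].sum())
    micro_area = int(areas[~macro].sum())
    return MacroMicroSplit(
        threshold=diameter_threshold,
        units=units,
        macro_count=int(macro.sum()),
        micro_count=int((~macro).sum()),
        macro_area_px=macro_area,
        micro_area_px=micro_area,
        macro_area_fraction=macro_area / vs.total_fat_px,
        micro_area_fraction=micro_area / vs.total_fat_px,
    )
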