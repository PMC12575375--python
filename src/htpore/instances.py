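"""From pore masks to filtered, labeled instances.

Connected pore detections are split with a watershed on the negated
Euclidean distance transform (seeds at distance maxima), elongated labels
(eccentricity of the moment-matched ellipse > 0.8) are discarded as false
detections, and among the analysed slices only the one with the most
structures is retained, so each field contributes one independent
measurement.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.measure import regionprops
from skimage.segmentation import watershed

logger = logging.getLogger(__name__)

#: 8-connectivity structuring element for components and labels
_CONN8 = np.ones((3, 3), dtype=int)

STRUCTURE_COLUMNS = ["label_id", "area_px", "area_um2", "eccentricity",
                     "centroid_y", "centroid_x"]


@dataclasses.dataclass
class StructureTable:
    """Per-instance measurements of the circular structures on one slice."""

    slice_index: int
    rows: pd.DataFrame  # columns STRUCTURE_COLUMNS

    def __post_init__(self) -> None:
        missing = set(STRUCTURE_COLUMNS) - set(self.rows.columns)
        if missing:
            raise ValueError(f"missing columns {sorted(missing)}")

    @property
    def n_structures(self) -> int:
        return len(self.rows)

    @property
    def areas_um2(self) -> list[float]:
        return self.rows["area_um2"].tolist()


def split_instances(
    pore_mask: np.ndarray,
    min_seed_distance_px: int = 5,
    min_area_px: int = 4,
) -> np.ndarray:
    """Label a binary pore mask, splitting touching structures by watershed.

    Components smaller than ``min_area_px`` pixels are dropped first as
    single-pixel noise. Seeds are local maxima of the Euclidean distance
    transform at least ``min_seed_distance_px`` apart; the watershed floods
    the negated distance transform within the mask, so the union of labels
    equals the (cleaned) mask and spuriously connected structures separate
    at their waist.
    """
    mask = np.asarray(pore_mask).astype(bool)
    if mask.ndim != 2:
        raise ValueError("pore mask must be 2D")
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    if min_area_px > 1:
        comp, n = ndi.label(mask, structure=_CONN8)
        sizes = np.bincount(comp.ravel())
        small = np.flatnonzero(sizes < min_area_px)
        mask = mask & ~np.isin(comp, small[small > 0])
        if not mask.any():
            return np.zeros(mask.shape, dtype=np.int32)
    distance = ndi.distance_transform_edt(mask)
    seed_coords = peak_local_max(
        distance,
        min_distance=min_seed_distance_px,
        labels=mask,
        exclude_border=False,
    )
    seeds = np.zeros(mask.shape, dtype=np.int32)
    seeds[tuple(seed_coords.T)] = np.arange(1, len(seed_coords) + 1)
    labeled = watershed(-distance, markers=seeds, mask=mask, connectivity=2)
    # components with no seed (flat plateaus swallowed by NMS) keep one label
    orphan = mask & (labeled == 0)
    if orphan.any():
        comp, n = ndi.label(orphan, structure=_CONN8)
        labeled = labeled + np.where(comp > 0, comp + labeled.max(), 0)
    return labeled.astype(np.int32)


def filter_labels(
    labeled: np.ndarray,
    pixel_size_xy_um: float,
    ecc_max: float = 0.8,
    slice_index: int = 0,
) -> StructureTable:
    """Measure labels and drop elongated (eccentricity > ecc_max) ones.

    Eccentricity is that of the ellipse with matching second central
    moments; single-pixel labels, whose moments are degenerate, are removed
    with a logged reason. Areas convert as ``area_px * pixel_size_xy_um**2``.
    """
    if pixel_size_xy_um <= 0:
        raise ValueError("pixel size must be positive")
    labeled = np.asarray(labeled)
    rows = []
    for prop in regionprops(labeled):
        if prop.area < 2:
            logger.info("label %d removed: single pixel, degenerate moments",
                        prop.label)
            continue
        ecc = float(prop.eccentricity)
        if ecc > ecc_max:
            logger.info("label %d removed: eccentricity %.3f > %.2f",
                        prop.label, ecc, ecc_max)
            continue
        cy, cx = prop.centroid
        rows.append(
            {
                "label_id": int(prop.label),
                "area_px": int(prop.area),
                "area_um2": float(prop.area * pixel_size_xy_um**2),
                "eccentricity": ecc,
                "centroid_y": float(cy),
                "centroid_x": float(cx),
            }
        )
    frame = pd.DataFrame(rows, columns=STRUCTURE_COLUMNS)
    return StructureTable(slice_index=slice_index, rows=frame)


def pick_best_slice(tables: list[StructureTable]) -> StructureTable:
    """Keep only the slice with the most structures (ties: lowest index)."""
    if not tables:
        raise ValueError("no slices to choose from")
    return min(tables, key=lambda t: (-t.n_structures, t.slice_index))
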