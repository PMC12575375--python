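"""Per-field quantification: cell counts and structures per cell.

Cell number in a field of view is estimated from the classifier's nucleus
and nucleolus masks: nucleoli lie inside nuclei, so the union of the two
masks is taken and every connected component with an area of more than
185 µm² counts as one nucleus. Combined with the retained-slice structure
table this yields per-field records (structure count, cell count,
structures per cell, area distribution) ready for group-level aggregation.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .instances import StructureTable

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class CellCountConfig:
    min_nucleus_area_um2: float = 185.0
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.min_nucleus_area_um2 <= 0:
            raise ValueError("min_nucleus_area_um2 must be positive")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclasses.dataclass
class QuantRecord:
    source_id: str
    slice_index: int
    n_structures: int
    n_cells: int
    structures_per_cell: Optional[float]
    areas_um2: list[float]
    acquisition_day: Optional[int] = None
    condition: Optional[str] = None


def count_cells(
    nucleus_mask: np.ndarray,
    nucleolus_mask: np.ndarray,
    pixel_size_xy_um: float,
    config: CellCountConfig = CellCountConfig(),
) -> int:
    """Count nuclei as connected areas of the nucleus∪nucleolus mask
    strictly larger than ``min_nucleus_area_um2``."""
    nucleus_mask = np.asarray(nucleus_mask).astype(bool)
    nucleolus_mask = np.asarray(nucleolus_mask).astype(bool)
    if nucleus_mask.shape != nucleolus_mask.shape:
        raise ValueError("mask shape mismatch")
    if pixel_size_xy_um <= 0:
        raise ValueError("pixel size must be positive")
    union = nucleus_mask | nucleolus_mask
    structure = (
        np.ones((3, 3), dtype=int)
        if config.connectivity == 8
        else ndi.generate_binary_structure(2, 1)
    )
    comp, n = ndi.label(union, structure=structure)
    if n == 0:
        return 0
    areas_px = np.bincount(comp.ravel())[1:]
    areas_um2 = areas_px * pixel_size_xy_um**2
    # strict "more than"; the relative guard keeps an area that is exactly
    # the threshold in real arithmetic from passing through float round-off
    # (one pixel is always many orders of magnitude larger than the guard)
    cutoff = config.min_nucleus_area_um2 * (1 + 1e-9)
    return int(np.count_nonzero(areas_um2 > cutoff))


def quantify_field(
    structures: StructureTable,
    n_cells: int,
    source_id: str = "",
    acquisition_day: Optional[int] = None,
    condition: Optional[str] = None,
) -> QuantRecord:
    """Summarize one field of view from its retained-slice structure table.

    With zero detected cells the per-cell rate is undefined (``None``); the
    field stays in the raw output but is flagged for exclusion from
    per-cell statistics.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be non-negative")
    per_cell: Optional[float]
    if n_cells > 0:
        per_cell = structures.n_structures / n_cells
    else:
        per_cell = None
        logger.warning(
            "field %s: no cells detected; structures_per_cell undefined", source_id
        )
    return QuantRecord(
        source_id=source_id,
        slice_index=structures.slice_index,
        n_structures=structures.n_structures,
        n_cells=n_cells,
        structures_per_cell=per_cell,
        areas_um2=structures.areas_um2,
        acquisition_day=acquisition_day,
        condition=condition,
    )


def aggregate(
    records: Sequence[QuantRecord], group_keys: Sequence[str] = ()
) -> pd.DataFrame:
    """Group-level summary of per-cell structure rates.

    Fields with undefined ``structures_per_cell`` (zero cells) are excluded
    from the statistics; the exclusion count is reported per group. Valid
    ``group_keys`` are the metadata columns ``condition`` and
    ``acquisition_day``.
    """
    allowed = {"condition", "acquisition_day"}
    bad = set(group_keys) - allowed
    if bad:
        raise KeyError(f"unknown group key(s) {sorted(bad)}")
    rows = []
    for r in records:
        rows.append(
            {
                "source_id": r.source_id,
                "condition": r.condition,
                "acquisition_day": r.acquisition_day,
                "structures_per_cell": (
                    r.structures_per_cell if r.n_cells > 0 else np.nan
                ),
                "n_structures": r.n_structures,
                "areas_um2": r.areas_um2,
            }
        )
    frame = pd.DataFrame(rows)
    keys = list(group_keys)
    if not keys:
        frame["_all"] = "all"
        keys = ["_all"]
    out = []
    for name, grp in frame.groupby(keys, dropna=False):
        vals = grp["structures_per_cell"].dropna()
        pooled = [a for areas in grp["areas_um2"] for a in areas]
        row = dict(zip(keys, name if isinstance(name, tuple) else (name,)))
        row.update(
            {
                "n_fields": len(grp),
                "n_excluded": int(grp["structures_per_cell"].isna().sum()),
                "mean_structures_per_cell": float(vals.mean()) if len(vals) else np.nan,
                "median_structures_per_cell": (
                    float(vals.median()) if len(vals) else np.nan
                ),
                "sd_structures_per_cell": (
                    float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
                ),
                "n": int(len(vals)),
                "mean_area_um2": float(np.mean(pooled)) if pooled else np.nan,
                "median_area_um2": float(np.median(pooled)) if pooled else np.nan,
            }
        )
        out.append(row)
    result = pd.DataFrame(out)
    return result.drop(columns=["_all"], errors="ignore")
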