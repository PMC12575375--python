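"""End-to-end segmentation of one HT z-stack.

Chains the stages: focus-slice selection, multiscale features, pixel
classification, watershed instance splitting with eccentricity filtering,
retained-slice selection, cell counting and per-field quantification.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from . import classify, focus, instances, quantify
from .features import compute_features
from .stack_io import RIStack


@dataclasses.dataclass
class SegmentationResult:
    focus: focus.FocusResult
    per_slice: dict[int, instances.StructureTable]
    predictions: dict[int, classify.PredictionMaps]
    retained: instances.StructureTable
    n_cells: int
    record: quantify.QuantRecord


def segment_stack(
    model: classify.PixelClassifier,
    stack: RIStack,
    focus_config: focus.FocusConfig = focus.FocusConfig(),
    cell_config: quantify.CellCountConfig = quantify.CellCountConfig(),
    min_seed_distance_px: int = 5,
    min_area_px: int = 4,
    ecc_max: float = 0.8,
    acquisition_day: Optional[int] = None,
    condition: Optional[str] = None,
) -> SegmentationResult:
    """Run the full analysis on one stack and summarize the field of view.

    Only slices passing the focus criterion are classified; among them the
    slice with the most detected circular structures is retained, and the
    cell count comes from that slice's nucleus/nucleolus masks.
    """
    fres = focus.select_focus(stack, focus_config)
    tables: dict[int, instances.StructureTable] = {}
    preds: dict[int, classify.PredictionMaps] = {}
    for z in fres.selected_slices:
        fs = compute_features(stack.voxels[z], model.feature_config)
        pred = classify.predict(model, fs)
        labeled = instances.split_instances(
            pred.pore_mask,
            min_seed_distance_px=min_seed_distance_px,
            min_area_px=min_area_px,
        )
        tables[z] = instances.filter_labels(
            labeled, stack.pixel_size_xy_um, ecc_max=ecc_max, slice_index=z
        )
        preds[z] = pred
    retained = instances.pick_best_slice(list(tables.values()))
    best_pred = preds[retained.slice_index]
    n_cells = quantify.count_cells(
        best_pred.nucleus_mask,
        best_pred.nucleolus_mask,
        stack.pixel_size_xy_um,
        cell_config,
    )
    record = quantify.quantify_field(
        retained,
        n_cells,
        source_id=stack.source_id,
        acquisition_day=acquisition_day,
        condition=condition,
    )
    return SegmentationResult(
        focus=fres,
        per_slice=tables,
        predictions=preds,
        retained=retained,
        n_cells=n_cells,
        record=record,
    )
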