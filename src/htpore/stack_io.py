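"""Reading and writing holotomography stacks, label masks, models and tables.

All containers carry explicit physical pixel sizes so that downstream area
measurements are always unit-aware. Axis order is (z, y, x) throughout and
slice indices are 0-based.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

#: class codes shared by every ground-truth mask and classifier in the package
CLASS_CODES: dict[int, str] = {
    0: "background",
    1: "circular_structure",
    2: "nucleus",
    3: "nucleolus",
}

MODEL_SCHEMA_VERSION = "htpore-model-1"
QUANT_SCHEMA_VERSION = "htpore-quant-1"

QUANT_COLUMNS = [
    "source_id",
    "slice_index",
    "n_structures",
    "n_cells",
    "structures_per_cell",
    "mean_area_um2",
    "median_area_um2",
    "total_area_um2",
    "acquisition_day",
    "condition",
]


@dataclasses.dataclass
class RIStack:
    """A 3D refractive-index image with physical pixel sizes.

    Parameters
    ----------
    voxels : ndarray, shape (z, y, x)
        Refractive-index values; must be finite.
    pixel_size_xy_um, pixel_size_z_um : float
        Lateral and axial voxel pitch in micrometres.
    source_id : str
        Identifier of the field of view (file stem, phantom seed, ...).
    """

    voxels: np.ndarray
    pixel_size_xy_um: float
    pixel_size_z_um: float
    source_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a (z, y, x) array, got ndim={self.voxels.ndim}")
        nz, ny, nx = self.voxels.shape
        if nz < 1 or ny < 2 or nx < 2:
            raise ValueError(f"stack too small: shape {self.voxels.shape}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("stack contains non-finite voxels")
        if not (self.pixel_size_xy_um > 0 and self.pixel_size_z_um > 0):
            raise ValueError("pixel sizes must be strictly positive")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def slice_shape(self) -> tuple[int, int]:
        return self.voxels.shape[1:]


@dataclasses.dataclass
class GroundTruthMask:
    """Per-pixel class labels aligned to one RI slice.

    ``labels`` holds the codes of :data:`CLASS_CODES`
    (0 background, 1 circular structure, 2 nucleus, 3 nucleolus).
    """

    labels: np.ndarray
    slice_index: int
    class_codes: Mapping[int, str] = dataclasses.field(
        default_factory=lambda: dict(CLASS_CODES)
    )

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-typed")
        bad = set(np.unique(self.labels)) - set(self.class_codes)
        if bad:
            raise ValueError(f"labels contain unknown class codes {sorted(bad)}")


def _resolution_to_pixel_size_um(page) -> float | None:
    """Recover the XY pixel size (µm) from TIFF resolution tags, if present."""
    try:
        xres = page.tags["XResolution"].value
        unit = page.tags["ResolutionUnit"].value
    except KeyError:
        return None
    num, den = (xres if isinstance(xres, tuple) else (xres, 1))
    if num == 0:
        return None
    per_unit = num / den
    # pixels per unit -> um per pixel
    unit = getattr(unit, "value", unit)
    if unit == 3:  # centimetre
        return 1e4 / per_unit
    if unit == 2:  # inch
        return 25_400.0 / per_unit
    return None


def write_stack(stack: RIStack, path: str | Path) -> None:
    """Write an :class:`RIStack` as a multi-page float32 TIFF.

    The XY pixel size goes into the TIFF resolution tags (pixels per cm);
    the axial spacing into the ImageJ-style metadata, and both are echoed in
    the image description for robustness.
    """
    path = Path(path)
    px_per_cm = 1e4 / stack.pixel_size_xy_um
    meta = {
        "pixel_size_xy_um": stack.pixel_size_xy_um,
        "pixel_size_z_um": stack.pixel_size_z_um,
        "source_id": stack.source_id,
    }
    tifffile.imwrite(
        path,
        stack.voxels.astype(np.float32),
        photometric="minisblack",
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
        description=json.dumps(meta),
    )


def read_stack(
    path: str | Path,
    pixel_size_override: tuple[float, float] | None = None,
) -> RIStack:
    """Read a multi-page TIFF into an :class:`RIStack`.

    Pixel sizes come from the file metadata; ``pixel_size_override``
    ((xy_um, z_um)) replaces them. A file without resolution metadata and
    without an override is rejected: areas without units are meaningless.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        shapes = {p.shape for p in tif.pages}
        if len(shapes) != 1:
            raise ValueError(f"ragged TIFF pages: {sorted(shapes)}")
        voxels = tif.asarray()
        if voxels.ndim == 2:
            voxels = voxels[None]
        if not np.issubdtype(voxels.dtype, np.number):
            raise ValueError("non-numeric TIFF data")
        xy_um = None
        z_um = None
        desc = tif.pages[0].description
        if desc:
            try:
                meta = json.loads(desc)
                xy_um = meta.get("pixel_size_xy_um")
                z_um = meta.get("pixel_size_z_um")
            except (json.JSONDecodeError, AttributeError):
                pass
        if xy_um is None:
            xy_um = _resolution_to_pixel_size_um(tif.pages[0])
    if pixel_size_override is not None:
        xy_um, z_um = pixel_size_override
    if xy_um is None or z_um is None:
        raise ValueError(
            "units unknown: no pixel-size metadata in file and no override given"
        )
    return RIStack(
        voxels=np.asarray(voxels, dtype=np.float32),
        pixel_size_xy_um=float(xy_um),
        pixel_size_z_um=float(z_um),
        source_id=path.stem,
    )


def write_mask(mask: GroundTruthMask, path: str | Path) -> None:
    """Write a class mask as an 8-bit label TIFF."""
    tifffile.imwrite(
        Path(path),
        mask.labels.astype(np.uint8),
        description=json.dumps({"slice_index": mask.slice_index}),
    )


def read_mask(path: str | Path, slice_index: int | None = None) -> GroundTruthMask:
    """Read an 8-bit label TIFF back into a :class:`GroundTruthMask`."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        labels = tif.asarray()
        if slice_index is None:
            try:
                slice_index = json.loads(tif.pages[0].description)["slice_index"]
            except (json.JSONDecodeError, KeyError, TypeError):
                slice_index = 0
    return GroundTruthMask(labels=labels.astype(np.int64), slice_index=int(slice_index))


def write_label_image(labels: np.ndarray, path: str | Path) -> None:
    """Write an instance label image as 16-bit TIFF."""
    labels = np.asarray(labels)
    if labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels; cannot store as 16-bit")
    tifffile.imwrite(Path(path), labels.astype(np.uint16))


def quant_records_to_frame(records: Sequence) -> pd.DataFrame:
    """Normalize a list of QuantRecord dataclasses into a tidy DataFrame.

    ``structures_per_cell`` is left missing (NaN -> empty CSV field) for
    fields with zero detected cells rather than coerced to 0.
    """
    rows = []
    for r in records:
        areas = list(r.areas_um2)
        rows.append(
            {
                "source_id": r.source_id,
                "slice_index": r.slice_index,
                "n_structures": r.n_structures,
                "n_cells": r.n_cells,
                "structures_per_cell": (
                    r.structures_per_cell if r.n_cells > 0 else np.nan
                ),
                "mean_area_um2": float(np.mean(areas)) if areas else np.nan,
                "median_area_um2": float(np.median(areas)) if areas else np.nan,
                "total_area_um2": float(np.sum(areas)) if areas else 0.0,
                "acquisition_day": r.acquisition_day,
                "condition": r.condition,
            }
        )
    return pd.DataFrame(rows, columns=QUANT_COLUMNS)


def write_quant_table(records: Sequence, path: str | Path) -> None:
    """Write per-field quantification records as CSV ("." decimal separator).

    An empty record list produces a header-only file.
    """
    frame = quant_records_to_frame(records)
    frame.to_csv(Path(path), index=False)


def read_quant_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))


def save_model(model, path: str | Path) -> None:
    """Serialize a trained pixel classifier with its feature configuration.

    The artifact embeds a schema-version string and the full feature
    configuration so a model can never be applied to mismatched features.
    """
    import joblib

    payload = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "feature_config": dataclasses.asdict(model.feature_config),
        "feature_names": list(model.feature_names_),
        "class_codes": dict(model.class_codes),
        "model": model,
    }
    joblib.dump(payload, Path(path))


def load_model(path: str | Path):
    import joblib

    payload = joblib.load(Path(path))
    version = payload.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema {version!r}")
    return payload["model"]
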