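"""Synthetic holotomography phantoms of adherent cells with exact ground truth.

The generator renders a field of non-overlapping cells on a virtual
coverslip as a refractive-index (RI) z-stack with the optical signature of
holotomographic imaging of endothelial cells: a watery background
(RI ~ 1.337), a cytoplasm slab of higher RI, a nucleus of intermediate RI
containing one or more dense, high-RI nucleoli, bright high-RI vesicles as
distractors, and — the detection target — circular transcellular pores whose
interior RI equals the background. Resolution is anisotropic (0.2 µm
laterally, 1 µm axially by default, 70 slices per stack) and slices away
from the focal plane receive increasing Gaussian defocus blur.

Every structure is rasterized from analytic geometry, so the per-slice
class masks and the per-instance table (areas in µm², parent cells) are
exact by construction. A single master seed drives all randomness through
named ``numpy`` seed-sequence streams, making output bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .stack_io import GroundTruthMask, RIStack


class FieldTooCrowdedError(RuntimeError):
    """Raised when non-overlapping cell placement fails after bounded retries."""


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic field of view.

    RI defaults follow the qualitative ordering seen in holotomograms of
    cultured endothelial cells — pores at background level, nucleus below
    cytoplasm, nucleoli and lipid-like vesicles high — with magnitudes
    typical of quantitative phase imaging of mammalian cells. They are
    configurable and never assumed by any downstream algorithm.
    """

    field_size_px: tuple[int, int] = (384, 384)
    n_slices: int = 70
    pixel_size_xy_um: float = 0.2
    pixel_size_z_um: float = 1.0
    n_cells: int = 2
    pores_per_cell_mean: float = 15.0
    pore_radius_um_range: tuple[float, float] = (0.5, 1.5)
    cell_radius_um_range: tuple[float, float] = (13.0, 16.0)
    nucleus_area_um2_range: tuple[float, float] = (205.0, 250.0)
    nucleoli_per_nucleus: tuple[int, int] = (1, 3)
    ri_background: float = 1.337
    ri_cytoplasm: float = 1.365
    ri_nucleus: float = 1.355
    ri_nucleolus: float = 1.39
    ri_vesicle: float = 1.42
    vesicles_per_cell_mean: float = 5.0
    noise_sd: float = 0.003
    blur_sigma_xy_px: float = 0.6
    blur_sigma_z_slices: float = 0.5
    focal_slice: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if not (
            self.ri_background
            < self.ri_nucleus
            < self.ri_cytoplasm
            < self.ri_nucleolus
            <= self.ri_vesicle
        ):
            raise ValueError(
                "RI ordering must satisfy background < nucleus < cytoplasm "
                "< nucleolus <= vesicle"
            )
        rmin, rmax = self.pore_radius_um_range
        if not 0 < rmin <= rmax:
            raise ValueError("pore radius range must satisfy 0 < min <= max")
        cmin, cmax = self.cell_radius_um_range
        if not 0 < cmin <= cmax:
            raise ValueError("cell radius range must satisfy 0 < min <= max")
        if rmin * 2 < self.pixel_size_xy_um:
            raise ValueError("zero-area pore request: radius below half a pixel")
        if not 0 <= self.focal_slice < self.n_slices:
            raise ValueError("focal_slice must lie within [0, n_slices)")
        if self.n_cells < 0 or self.pores_per_cell_mean < 0:
            raise ValueError("counts must be non-negative")
        if self.noise_sd < 0 or self.blur_sigma_xy_px < 0 or self.blur_sigma_z_slices < 0:
            raise ValueError("noise and blur parameters must be non-negative")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomSpec":
        d = json.loads(Path(path).read_text())
        for key in (
            "field_size_px",
            "pore_radius_um_range",
            "nucleoli_per_nucleus",
            "cell_radius_um_range",
            "nucleus_area_um2_range",
        ):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclasses.dataclass
class PhantomOutput:
    stack: RIStack
    truth: list[GroundTruthMask]  # one per slice
    instance_truth: pd.DataFrame  # type, instance_id, parent_cell, slice, area_um2
    instance_labels: np.ndarray  # (z, y, x) pore instance ids (0 = none)
    spec_echo: PhantomSpec

    def truth_volume(self) -> np.ndarray:
        return np.stack([m.labels for m in self.truth])

    def pores_per_cell(self) -> pd.Series:
        pores = self.instance_truth[self.instance_truth["type"] == "pore"]
        counts = pores.groupby("parent_cell").size()
        return counts.reindex(range(self.spec_echo.n_cells), fill_value=0)


# --- geometry helpers -------------------------------------------------------


def _ellipse_mask(shape, cy, cx, ry, rx, theta) -> np.ndarray:
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    y = yy - cy
    x = xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = x * ct + y * st
    v = -x * st + y * ct
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def _disk_mask(shape, cy, cx, r) -> np.ndarray:
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def _wobbly_cell_mask(shape, cy, cx, r_px, rng) -> np.ndarray:
    """Cell footprint: a radially perturbed disk (smoothed random polygon)."""
    n_harm = 5
    amp = rng.uniform(0.04, 0.12, size=n_harm)
    phase = rng.uniform(0, 2 * np.pi, size=n_harm)
    stretch = rng.uniform(0.75, 1.0)
    theta0 = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    y = yy - cy
    x = xx - cx
    ct, st = np.cos(theta0), np.sin(theta0)
    u = x * ct + y * st
    v = (-x * st + y * ct) / stretch
    ang = np.arctan2(v, u)
    rad = np.sqrt(u * u + v * v)
    boundary = r_px * (
        1.0 + sum(a * np.cos((k + 2) * ang + p) for k, (a, p) in enumerate(zip(amp, phase)))
    )
    return rad <= boundary


@dataclasses.dataclass
class _Cell:
    mask: np.ndarray  # 2D footprint
    z_lo: int  # first slice occupied (inclusive)
    z_hi: int  # last slice occupied (inclusive)
    nucleus: np.ndarray
    nucleus_z: tuple[int, int]
    nucleoli: list[np.ndarray]
    pores: list[np.ndarray]  # 2D disks, transcellular over [z_lo, z_hi]
    pore_radii_um: list[float]
    vesicles: list[tuple[np.ndarray, int, int]]  # mask, z_lo, z_hi
    pore_footprint: np.ndarray | None = None  # dilated union of pore disks


def _place_cells(spec: PhantomSpec, rng: np.random.Generator) -> list[_Cell]:
    shape = spec.field_size_px
    px = spec.pixel_size_xy_um
    occupied = np.zeros(shape, dtype=bool)
    cells: list[_Cell] = []
    max_retries = 200
    for _ in range(spec.n_cells):
        placed = False
        for _attempt in range(max_retries):
            r_px = rng.uniform(*spec.cell_radius_um_range) / px
            cy = rng.uniform(r_px * 0.9, shape[0] - r_px * 0.9)
            cx = rng.uniform(r_px * 0.9, shape[1] - r_px * 0.9)
            mask = _wobbly_cell_mask(shape, cy, cx, r_px, rng)
            grown = ndi.binary_dilation(mask, iterations=3)
            if not (grown & occupied).any():
                occupied |= grown
                placed = True
                break
        if not placed:
            raise FieldTooCrowdedError(
                f"could not place {spec.n_cells} non-overlapping cells "
                f"in a {shape} field after {max_retries} retries"
            )
        # axial extent: all cells sit on the substrate just below the focal
        # plane so the focal slice intersects every cell
        z_lo = max(0, spec.focal_slice - 2)
        thickness = int(rng.integers(6, 13))  # 6-12 um at 1 um/slice
        z_hi = min(spec.n_slices - 1, z_lo + thickness - 1)

        # nucleus: moment-smooth ellipse, area > the 185 um^2 counting rule;
        # kept near the cell centre so the wobbly rim never clips it
        nuc_area_um2 = rng.uniform(*spec.nucleus_area_um2_range)
        nr = np.sqrt(nuc_area_um2 / np.pi) / px
        aspect = rng.uniform(0.85, 1.0)
        off = r_px * 0.08
        ncy = cy + rng.uniform(-off, off)
        ncx = cx + rng.uniform(-off, off)
        nucleus = _ellipse_mask(
            shape, ncy, ncx, nr / np.sqrt(aspect), nr * np.sqrt(aspect),
            rng.uniform(0, np.pi),
        )
        nucleus &= ndi.binary_erosion(mask, iterations=2)
        nuc_mid = (z_lo + z_hi) // 2
        nz_half = max(1, (z_hi - z_lo) // 3)
        nucleus_z = (
            min(max(z_lo, nuc_mid - nz_half), spec.focal_slice),
            max(min(z_hi, nuc_mid + nz_half), spec.focal_slice),
        )

        # nucleoli inside the nucleus
        n_nucleoli = int(rng.integers(spec.nucleoli_per_nucleus[0],
                                      spec.nucleoli_per_nucleus[1] + 1))
        nucleoli = []
        inner = ndi.binary_erosion(nucleus, iterations=6)
        inner_pts = np.argwhere(inner)
        for _n in range(n_nucleoli):
            if inner_pts.size == 0:
                break
            py, pxx = inner_pts[rng.integers(len(inner_pts))]
            r_nl = rng.uniform(0.8, 1.4) / px
            nl = _disk_mask(shape, py, pxx, r_nl) & nucleus
            if nl.any():
                nucleoli.append(nl)

        cells.append(
            _Cell(mask=mask, z_lo=z_lo, z_hi=z_hi, nucleus=nucleus,
                  nucleus_z=nucleus_z, nucleoli=nucleoli, pores=[],
                  pore_radii_um=[], vesicles=[])
        )
    return cells


def _place_pores(spec: PhantomSpec, cells: list[_Cell], rng: np.random.Generator) -> None:
    """Scatter non-overlapping transcellular pores in each cell's cytoplasm."""
    shape = spec.field_size_px
    px = spec.pixel_size_xy_um
    for cell in cells:
        n_pores = int(rng.poisson(spec.pores_per_cell_mean))
        # keep pores clear of the nucleus and the cell rim
        allowed = ndi.binary_erosion(cell.mask, iterations=4) & ~ndi.binary_dilation(
            cell.nucleus, iterations=3
        )
        pts = np.argwhere(allowed)
        taken = np.zeros(shape, dtype=bool)
        for _p in range(n_pores):
            for _attempt in range(60):
                r_um = rng.uniform(*spec.pore_radius_um_range)
                r_px = r_um / px
                if len(pts) == 0:
                    break
                py, pxx = pts[rng.integers(len(pts))]
                disk = _disk_mask(shape, py, pxx, r_px)
                # separation margin keeps instances resolvable by watershed
                margin = ndi.binary_dilation(disk, iterations=3)
                if disk.any() and (disk <= allowed).all() and not (margin & taken).any():
                    cell.pores.append(disk)
                    cell.pore_radii_um.append(r_um)
                    taken |= margin
                    break
        cell.pore_footprint = taken


def _place_vesicles(spec: PhantomSpec, cells: list[_Cell], rng: np.random.Generator) -> None:
    px = spec.pixel_size_xy_um
    shape = spec.field_size_px
    for cell in cells:
        n_ves = int(rng.poisson(spec.vesicles_per_cell_mean))
        # vesicles live in the cytoplasm, clear of nucleus and pores
        allowed = (
            ndi.binary_erosion(cell.mask, iterations=2)
            & ~ndi.binary_dilation(cell.nucleus, iterations=2)
        )
        if cell.pore_footprint is not None:
            allowed &= ~cell.pore_footprint
        pts = np.argwhere(allowed)
        for _v in range(n_ves):
            if len(pts) == 0:
                break
            py, pxx = pts[rng.integers(len(pts))]
            r_px = rng.uniform(0.3, 0.8) / px
            ves = _disk_mask(shape, py, pxx, r_px) & allowed
            if not ves.any():
                continue
            z0 = int(rng.integers(cell.z_lo, cell.z_hi + 1))
            z1 = min(cell.z_hi, z0 + int(rng.integers(1, 3)))
            cell.vesicles.append((ves, z0, z1))


def render_defocus(
    stack_sharp: RIStack,
    blur_sigma_xy_px: float,
    blur_sigma_z_slices: float,
    focal_slice: int,
) -> RIStack:
    """Apply z-dependent lateral Gaussian defocus to a sharp stack.

    Slice ``z`` is blurred in XY with
    ``sigma(z) = blur_sigma_xy_px + blur_sigma_z_slices * |z - focal_slice|``,
    a normalized kernel with reflective boundaries, so each slice's mean is
    preserved and blur grows monotonically away from the focal plane. Both
    sigmas zero is the identity.
    """
    if blur_sigma_xy_px < 0 or blur_sigma_z_slices < 0:
        raise ValueError("blur sigmas must be non-negative")
    out = np.array(stack_sharp.voxels, dtype=np.float64, copy=True)
    for z in range(out.shape[0]):
        sigma = blur_sigma_xy_px + blur_sigma_z_slices * abs(z - focal_slice)
        if sigma > 0:
            out[z] = ndi.gaussian_filter(out[z], sigma, mode="reflect")
    return RIStack(
        voxels=out.astype(np.float32),
        pixel_size_xy_um=stack_sharp.pixel_size_xy_um,
        pixel_size_z_um=stack_sharp.pixel_size_z_um,
        source_id=stack_sharp.source_id,
    )


def generate_phantom(spec: PhantomSpec) -> PhantomOutput:
    """Render one synthetic field of view with exact ground truth.

    Randomness derives from ``spec.seed`` through named child streams
    (geometry, vesicles, noise), so identical specs give bit-identical
    output regardless of the order in which other phantoms are generated.
    """
    ss = np.random.SeedSequence(spec.seed)
    geom_rng, pore_rng, ves_rng, noise_rng = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    shape = spec.field_size_px
    nz = spec.n_slices

    cells = _place_cells(spec, geom_rng) if spec.n_cells else []
    _place_pores(spec, cells, pore_rng)
    _place_vesicles(spec, cells, ves_rng)

    ri = np.full((nz, *shape), spec.ri_background, dtype=np.float64)
    labels = np.zeros((nz, *shape), dtype=np.uint8)
    pore_ids = np.zeros((nz, *shape), dtype=np.int32)

    records = []
    pore_id = 0
    px_area = spec.pixel_size_xy_um**2
    for ci, cell in enumerate(cells):
        zs = range(cell.z_lo, cell.z_hi + 1)
        for z in zs:
            ri[z][cell.mask] = spec.ri_cytoplasm
            if cell.nucleus_z[0] <= z <= cell.nucleus_z[1]:
                ri[z][cell.nucleus] = spec.ri_nucleus
                labels[z][cell.nucleus] = 2
                for nl in cell.nucleoli:
                    ri[z][nl] = spec.ri_nucleolus
                    labels[z][nl] = 3
        for ves, z0, z1 in cell.vesicles:
            for z in range(z0, z1 + 1):
                ri[z][ves] = spec.ri_vesicle
        # transcellular pores: all slices intersecting the cell footprint
        for disk, r_um in zip(cell.pores, cell.pore_radii_um):
            pore_id += 1
            for z in zs:
                ri[z][disk] = spec.ri_background
                labels[z][disk] = 1
                pore_ids[z][disk] = pore_id
            records.append(
                {
                    "type": "pore",
                    "instance_id": pore_id,
                    "parent_cell": ci,
                    "slice": spec.focal_slice,
                    "area_um2": float(disk.sum() * px_area),
                    "radius_um": r_um,
                }
            )
        records.append(
            {
                "type": "nucleus",
                "instance_id": -(ci + 1),
                "parent_cell": ci,
                "slice": spec.focal_slice,
                "area_um2": float(cell.nucleus.sum() * px_area),
                "radius_um": np.nan,
            }
        )
        for nl in cell.nucleoli:
            records.append(
                {
                    "type": "nucleolus",
                    "instance_id": 0,
                    "parent_cell": ci,
                    "slice": spec.focal_slice,
                    "area_um2": float(nl.sum() * px_area),
                    "radius_um": np.nan,
                }
            )

    stack = RIStack(
        voxels=ri.astype(np.float32),
        pixel_size_xy_um=spec.pixel_size_xy_um,
        pixel_size_z_um=spec.pixel_size_z_um,
        source_id=f"phantom-seed{spec.seed}",
    )
    if spec.blur_sigma_xy_px > 0 or spec.blur_sigma_z_slices > 0:
        stack = render_defocus(
            stack, spec.blur_sigma_xy_px, spec.blur_sigma_z_slices, spec.focal_slice
        )
    if spec.noise_sd > 0:
        noisy = stack.voxels + noise_rng.normal(
            0.0, spec.noise_sd, size=stack.voxels.shape
        )
        stack = RIStack(
            voxels=noisy.astype(np.float32),
            pixel_size_xy_um=spec.pixel_size_xy_um,
            pixel_size_z_um=spec.pixel_size_z_um,
            source_id=stack.source_id,
        )

    truth = [
        GroundTruthMask(labels=labels[z].astype(np.int64), slice_index=z)
        for z in range(nz)
    ]
    instance_truth = pd.DataFrame(
        records,
        columns=["type", "instance_id", "parent_cell", "slice", "area_um2", "radius_um"],
    )
    return PhantomOutput(
        stack=stack,
        truth=truth,
        instance_truth=instance_truth,
        instance_labels=pore_ids,
        spec_echo=spec,
    )


def write_phantom(out: PhantomOutput, directory: str | Path, prefix: str = "field") -> None:
    """Write stack (float32 TIFF), truth (8-bit TIFF), instances (CSV), spec (JSON)."""
    from . import stack_io
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stack_io.write_stack(out.stack, directory / f"{prefix}_stack.tif")
    tifffile.imwrite(
        directory / f"{prefix}_truth.tif", out.truth_volume().astype(np.uint8)
    )
    out.instance_truth.to_csv(directory / f"{prefix}_instances.csv", index=False)
    out.spec_echo.to_json(directory / f"{prefix}_spec.json")
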