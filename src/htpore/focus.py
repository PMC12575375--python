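"""In-focus slice selection for HT z-stacks.

Each slice gets a scalar focus measure — by default the mean absolute
response of the 2D Laplacian — and slices are selected by comparing the
measure to ``mean + n * std`` over the whole stack, with ``n`` chosen as the
largest candidate (default 3, 2, 1, 0) that leaves at least one slice
selected. If even ``n = 0`` selects nothing (a flat metric), the sharpest
slice is returned as a fallback.
"""

from __future__ import annotations

import dataclasses
from typing import Literal, Sequence, Union

import numpy as np
from scipy import ndimage as ndi

from .stack_io import RIStack

_KERNELS = {
    "four_connected": np.array(
        [[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]]
    ),
    "eight_connected": np.array(
        [[1.0, 1.0, 1.0], [1.0, -8.0, 1.0], [1.0, 1.0, 1.0]]
    ),
}


@dataclasses.dataclass(frozen=True)
class FocusConfig:
    """Configuration of the focus measure and the slice-selection rule."""

    n_candidates: tuple[int, ...] = (3, 2, 1, 0)
    laplacian_kernel: Literal["four_connected", "eight_connected"] = "four_connected"
    magnitude: Literal["mean_abs", "variance"] = "mean_abs"

    def __post_init__(self) -> None:
        ns = tuple(self.n_candidates)
        if len(ns) == 0:
            raise ValueError("n_candidates must be non-empty")
        if any(n < 0 for n in ns):
            raise ValueError("n_candidates must be non-negative")
        if any(a <= b for a, b in zip(ns, ns[1:])):
            raise ValueError("n_candidates must be strictly decreasing")
        if self.laplacian_kernel not in _KERNELS:
            raise ValueError(f"unknown kernel {self.laplacian_kernel!r}")


@dataclasses.dataclass
class FocusResult:
    metric_per_slice: np.ndarray
    chosen_n: Union[int, Literal["fallback"]]
    selected_slices: tuple[int, ...]


def focus_metric(stack: RIStack, config: FocusConfig = FocusConfig()) -> np.ndarray:
    """Per-slice focus measure from the 2D Laplacian (reflective boundary).

    Adding a constant to all voxels leaves the metric unchanged: the
    Laplacian annihilates constants.
    """
    kernel = _KERNELS[config.laplacian_kernel]
    out = np.empty(stack.n_slices, dtype=float)
    for z in range(stack.n_slices):
        lap = ndi.convolve(np.asarray(stack.voxels[z], dtype=float), kernel, mode="reflect")
        if config.magnitude == "mean_abs":
            out[z] = np.mean(np.abs(lap))
        else:
            out[z] = np.var(lap)
    return out


def select_slices(
    metric: Sequence[float], config: FocusConfig = FocusConfig()
) -> FocusResult:
    """Pick in-focus slices by the ``metric > mean + n*std`` rule.

    ``n`` runs over ``config.n_candidates`` in decreasing order; the first
    value yielding a non-empty selection wins. The standard deviation is the
    population (ddof=0) one, and the inequality is strict. If no candidate
    selects anything the argmax slice is returned (ties to the lowest index)
    with ``chosen_n = "fallback"``.
    """
    metric = np.asarray(metric, dtype=float)
    if metric.ndim != 1 or metric.size < 1:
        raise ValueError("metric must be a non-empty 1D array")
    mean = metric.mean()
    std = metric.std()  # population std, ddof=0
    for n in config.n_candidates:
        selected = np.flatnonzero(metric > mean + n * std)
        if selected.size:
            return FocusResult(metric, int(n), tuple(int(i) for i in selected))
    return FocusResult(metric, "fallback", (int(np.argmax(metric)),))


def select_focus(
    stack: RIStack, config: FocusConfig = FocusConfig()
) -> FocusResult:
    """Convenience wrapper: metric computation followed by slice selection."""
    return select_slices(focus_metric(stack, config), config)
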