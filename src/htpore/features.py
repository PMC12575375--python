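"""Per-pixel multiscale features for a single 2D refractive-index slice.

The feature vector follows the trainable-segmentation convention: the raw
image plus, at a doubling ladder of Gaussian scales, local intensity
(Gaussian smoothing), edge strength (Gaussian gradient magnitude) and
texture (the two eigenvalues of the Gaussian-smoothed Hessian). Kernel
ladders start at a minimum sigma and double until the maximum: intensity
spans 0.5-1024 px, edges and texture 0.5-32 px, which with the raw channel
gives 1 + 12 + 7 + 2*7 = 34 channels.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage as ndi


@dataclasses.dataclass(frozen=True)
class FeatureConfig:
    include_raw_ri: bool = True
    intensity_kernels: tuple[float, float] = (0.5, 1024.0)
    texture_kernels: tuple[float, float] = (0.5, 32.0)
    edge_kernels: tuple[float, float] = (0.5, 32.0)

    def channel_names(self) -> list[str]:
        """Deterministic, unique channel names in computation order."""
        names: list[str] = []
        if self.include_raw_ri:
            names.append("ri_raw")
        names += [f"intensity_s{s:g}" for s in expand_kernels(*self.intensity_kernels)]
        names += [f"edges_s{s:g}" for s in expand_kernels(*self.edge_kernels)]
        for s in expand_kernels(*self.texture_kernels):
            names += [f"texture_s{s:g}_ev1", f"texture_s{s:g}_ev2"]
        return names


@dataclasses.dataclass
class FeatureStack:
    values: np.ndarray  # (n_features, y, x)
    names: list[str]
    config_echo: FeatureConfig

    def __post_init__(self) -> None:
        if self.values.shape[0] != len(self.names):
            raise ValueError("channel count does not match names")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate channel names")

    def as_table(self) -> np.ndarray:
        """Pixels as rows, features as columns — the classifier's input."""
        return self.values.reshape(self.values.shape[0], -1).T


def expand_kernels(min_sigma: float, max_sigma: float) -> list[float]:
    """Kernel ladder: ``min * 2**k`` for every k with ``min * 2**k <= max``."""
    if not 0 < min_sigma <= max_sigma:
        raise ValueError("need 0 < min <= max")
    scales = []
    s = float(min_sigma)
    # tiny tolerance so min*2**k == max survives float rounding
    while s <= max_sigma * (1 + 1e-12):
        scales.append(s)
        s *= 2.0
    return scales


def _clamped_sigma(sigma: float, shape: tuple[int, int]) -> float:
    limit = float(max(shape))
    if sigma > limit:
        warnings.warn(
            f"feature scale sigma={sigma:g} exceeds image extent {limit:g}; clamped",
            stacklevel=3,
        )
        return limit
    return sigma


def _hessian_eigenvalues(img: np.ndarray, sigma: float) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (descending) of the Hessian of the Gaussian-smoothed image.

    Second derivatives are taken by central differences on the smoothed
    image (the trainable-segmentation convention); differencing, unlike
    scipy's truncated derivative-of-Gaussian kernels, exactly annihilates
    constant offsets.
    """
    smoothed = ndi.gaussian_filter(img, sigma, mode="reflect")
    gy, gx = np.gradient(smoothed)
    hyy, hyx = np.gradient(gy)
    hxy, hxx = np.gradient(gx)
    hxy = 0.5 * (hyx + hxy)  # symmetrize edge rows where differencing differs
    half_trace = (hyy + hxx) / 2.0
    disc = np.sqrt(((hyy - hxx) / 2.0) ** 2 + hxy**2)
    return half_trace + disc, half_trace - disc


def compute_features(
    image: np.ndarray, config: FeatureConfig = FeatureConfig()
) -> FeatureStack:
    """Compute the multiscale feature stack for one 2D slice.

    All filters use reflective boundary handling; sigmas larger than the
    image extent are clamped with a warning. The raw-RI channel is the input
    slice itself, bit-identical.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("expected a 2D slice")
    if not np.all(np.isfinite(image)):
        raise ValueError("non-finite input")
    channels: list[np.ndarray] = []
    if config.include_raw_ri:
        channels.append(image.copy())
    for s in expand_kernels(*config.intensity_kernels):
        s = _clamped_sigma(s, image.shape)
        channels.append(ndi.gaussian_filter(image, s, mode="reflect"))
    for s in expand_kernels(*config.edge_kernels):
        s = _clamped_sigma(s, image.shape)
        channels.append(ndi.gaussian_gradient_magnitude(image, s, mode="reflect"))
    for s in expand_kernels(*config.texture_kernels):
        s = _clamped_sigma(s, image.shape)
        ev1, ev2 = _hessian_eigenvalues(image, s)
        channels += [ev1, ev2]
    values = np.stack(channels).astype(np.float32)
    return FeatureStack(values=values, names=config.channel_names(), config_echo=config)
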