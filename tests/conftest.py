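import dataclasses
import warnings

import numpy as np
import pytest

from htpore.phantom import PhantomSpec, generate_phantom


def small_spec(**overrides) -> PhantomSpec:
    """A fast, small phantom configuration for unit tests."""
    base = dict(
        field_size_px=(160, 160),
        n_slices=12,
        n_cells=1,
        pores_per_cell_mean=5.0,
        cell_radius_um_range=(9.0, 11.0),
        nucleus_area_um2_range=(120.0, 150.0),
        vesicles_per_cell_mean=2.0,
        focal_slice=4,
        seed=123,
    )
    base.update(overrides)
    return PhantomSpec(**base)


@pytest.fixture(scope="session")
def small_phantom():
    return generate_phantom(small_spec())


@pytest.fixture(autouse=True)
def _quiet_large_sigma_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="feature scale sigma", category=UserWarning
        )
        yield
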