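import numpy as np
import pytest

from senescan.features import Mask
from senescan.synthcells import SynthConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def disk_image(
    size: int = 64,
    radius: float = 20.0,
    offset: float = -40.0,
    background: float = 100.0,
    center: tuple[float, float] | None = None,
) -> np.ndarray:
    """Hard-edged disk rendered on a uniform background (analytic oracle
    geometry: pixel centers inside the radius belong to the disk)."""
    if center is None:
        center = ((size - 1) / 2, (size - 1) / 2)
    yy, xx = np.mgrid[0:size, 0:size]
    inside = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2
    img = np.full((size, size), background, dtype=float)
    img[inside] += offset
    return img


def disk_mask(size: int = 64, radius: float = 20.0, center=None) -> Mask:
    if center is None:
        center = ((size - 1) / 2, (size - 1) / 2)
    yy, xx = np.mgrid[0:size, 0:size]
    return Mask((yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2)


def tiny_synth_config(**overrides) -> SynthConfig:
    """A small, fast, fully-featured synthetic population for pipeline tests."""
    d = {
        "channels": ["BF", "DAPI", "gH2AX", "HMGB1"],
        "image_size_px": 128,
        "seed": 0,
        "populations": [
            {
                "name": "stained",
                "n_cells": 30,
                "senescent_fraction": 0.8,
                "area_um2_mean": 150.0,
                "foci": {"pos_fraction": 0.5},
                "markers": {
                    "HMGB1": {"p_pos_given_sen": 0.05, "p_pos_given_nonsen": 0.9}
                },
            },
            {
                "name": "unstained",
                "n_cells": 60,
                "unstained": True,
                "area_um2_mean": 150.0,
            },
        ],
    }
    d.update(overrides)
    return SynthConfig.from_dict(d)
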