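"""Shared fixtures and small builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from petlymph.volume import PETVolume


def make_volume(arr, spacing=(4.0, 4.0, 4.0), units="suv", meta=None) -> PETVolume:
    return PETVolume(voxels=np.asarray(arr, dtype=float), spacing=spacing,
                     units=units, meta=meta or {})


def gaussian_bump(shape, center, sigma, amplitude):
    """Additive 3-D Gaussian bump used to build tiny synthetic scans."""
    grids = np.ix_(*(np.arange(n) for n in shape))
    r2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return amplitude * np.exp(-r2 / (2.0 * sigma ** 2))


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
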