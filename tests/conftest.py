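"""Shared fixtures: tiny grids, rings and toy linear systems.

Everything is generated programmatically and seeded; no fixture files.
"""

from __future__ import annotations

import numpy as np
import pytest

from binpat.forward import TransducerModel, build_system_matrix
from binpat.geometry import AcquisitionSettings, make_detector_ring, make_grid


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def acquisition():
    """The standard sampling: 512 samples at 50 ns, 1500 m/s."""
    return AcquisitionSettings()


@pytest.fixture(scope="session")
def transducer():
    return TransducerModel()


@pytest.fixture(scope="session")
def small_grid():
    """A 32x32 grid over the 20.1 mm field of view."""
    return make_grid(32, 32, 20.1 / 32)


@pytest.fixture(scope="session")
def small_ring():
    return make_detector_ring(16, 22.0)


@pytest.fixture(scope="session")
def small_operator(small_grid, small_ring, acquisition, transducer):
    """A light tomographic operator (16 detectors x 512 samples, 1024 px)."""
    return build_system_matrix(small_grid, small_ring, acquisition, transducer)


@pytest.fixture(scope="session")
def toy_dense(rng):
    """Well-conditioned 16x9 dense system with a known solution."""
    A = rng.standard_normal((16, 9))
    x_true = rng.standard_normal(9)
    return A, x_true, A @ x_true
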