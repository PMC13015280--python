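import numpy as np
import pytest

from mesocondense import SimulationParams


@pytest.fixture
def params():
    """Small, fast parameter set used by most unit tests."""
    return SimulationParams(n_steps=50, seed=123)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def rigid_transform(points, angle, shift):
    """Rotate by angle then translate; used by equivariance tests."""
    c, s = np.cos(angle), np.sin(angle)
    Rm = np.array([[c, -s], [s, c]])
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return pts @ Rm.T + np.asarray(shift)
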