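import numpy as np
import pytest

from csmri import (
    CoilSet,
    KSpaceData,
    ProtocolParams,
    SamplingMask,
    make_phantom,
    simulate_coils,
)
from csmri.operators import SystemOperator


@pytest.fixture(scope="session")
def phantom64():
    return make_phantom((64, 64), n_lesions=2, seed=3)


@pytest.fixture(scope="session")
def coils64():
    return simulate_coils((64, 64), 8, seed=4)


@pytest.fixture(scope="session")
def params64():
    return ProtocolParams(matrix_read=64, matrix_pe=64, acceleration=3.0, n_acs=24)


@pytest.fixture
def uniform_coil():
    def _make(shape):
        return CoilSet(
            np.ones((1, *shape), dtype=complex), np.ones(shape, dtype=bool)
        )

    return _make


@pytest.fixture
def tiny_problem(uniform_coil):
    """16x16 single-coil undersampled problem with known simulated data:
    a small elliptical object with smooth phase, 9 of 16 lines sampled."""
    shape = (16, 16)
    rng = np.random.default_rng(0)
    yy, xx = np.mgrid[0:16, 0:16]
    img = np.zeros(shape, dtype=complex)
    img[((yy - 8) / 6.0) ** 2 + ((xx - 8) / 5.0) ** 2 <= 1] = 0.8
    img *= np.exp(1j * 0.3 * (xx / 16))
    coil = uniform_coil(shape)
    lines = np.union1d(np.sort(rng.choice(16, 8, replace=False)), [8])
    mask = SamplingMask(16, lines, "variable_density")
    op = SystemOperator(coil, mask, shape)
    data = op.forward(img)
    ks = KSpaceData(data, mask, np.zeros(mask.n_sampled))
    return img, coil, mask, ks
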