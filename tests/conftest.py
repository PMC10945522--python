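import warnings

import numpy as np
import pytest

from chromion.fixtures import make_fixture
from chromion.potentials import ForceField

warnings.filterwarnings("ignore", message="non-neutral box")


def finite_difference_forces(energy_fn, x, h=1e-5):
    """Central-difference negative gradient of a scalar energy function."""
    num = np.zeros_like(x)
    for i in range(x.shape[0]):
        for d in range(3):
            xp = x.copy(); xp[i, d] += h
            xm = x.copy(); xm[i, d] -= h
            num[i, d] = -(energy_fn(xp) - energy_fn(xm)) / (2.0 * h)
    return num


def max_relative_force_error(ff: ForceField, x) -> float:
    _, F = ff.energy_forces(x)
    num = finite_difference_forces(lambda xx: ff.energy_forces(xx)[0], x)
    return float(np.abs(num - F).max() / np.abs(F).max())


@pytest.fixture(scope="session")
def mini_protein():
    top, state, extras = make_fixture("mini_protein")
    return top, state, extras


@pytest.fixture(scope="session")
def short_duplex():
    top, state, extras = make_fixture("short_duplex", {"n_bp": 8})
    return top, state, extras


@pytest.fixture(scope="session")
def toy_dinucleosome():
    return make_fixture("toy_dinucleosome")
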