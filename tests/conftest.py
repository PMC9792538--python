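import numpy as np
import pytest

from mfbrain import (
    CascadeSpec,
    GrayImage,
    MeasureGrid,
    analyze_measure,
    cascade_closed_form,
    cascade_measure,
    default_q_grid,
)

UNEQUAL_WEIGHTS = (0.4, 0.3, 0.2, 0.1)


@pytest.fixture(scope="session")
def q3():
    """Moment grid [-3, 3] used for oracle comparisons."""
    return default_q_grid(-3.0, 3.0, 0.25)


@pytest.fixture(scope="session")
def cascade7():
    """Deterministic depth-7 quadrant cascade with unequal weights."""
    return cascade_measure(CascadeSpec(UNEQUAL_WEIGHTS, depth=7))


@pytest.fixture(scope="session")
def cascade7_spectra(cascade7, q3):
    return analyze_measure(cascade7, q_grid=q3)


@pytest.fixture(scope="session")
def cascade_oracle(q3):
    return cascade_closed_form(UNEQUAL_WEIGHTS, q3)


@pytest.fixture(scope="session")
def uniform64():
    """Uniform (space-filling) measure on a 64x64 grid."""
    return MeasureGrid(np.full((64, 64), 1.0 / 4096))


@pytest.fixture()
def gradient_image():
    """A smooth 32x32 ramp image spanning [0, 1]."""
    g = np.linspace(0.0, 1.0, 32)
    return GrayImage(np.tile(g, (32, 1)))
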