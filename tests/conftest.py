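import numpy as np
import pytest

from sobpkit import (
    RBEParams,
    SOBPSpec,
    build_sobp,
    compose,
    make_grid,
    rbe_weighted_dose,
)

DEFAULT_DISTAL_RANGE = 150.0


@pytest.fixture(scope="session")
def grid():
    return make_grid(0.0, 165.0, 0.1)


@pytest.fixture(scope="session")
def default_beam(grid):
    """The canonical 4-peak SOBP: distal range 150 mm, 6 mm spacing."""
    return build_sobp(SOBPSpec(distal_range=DEFAULT_DISTAL_RANGE), grid)


@pytest.fixture(scope="session")
def rbe_params():
    return RBEParams()


@pytest.fixture(scope="session")
def physical_curve(default_beam, grid):
    return compose(default_beam, grid)


@pytest.fixture(scope="session")
def biological_curve(default_beam, rbe_params, grid):
    return rbe_weighted_dose(default_beam, rbe_params, grid)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)
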