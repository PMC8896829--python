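import numpy as np
import pytest

from furrowsim import (
    GeometryParams,
    ModelParams,
    build_initial_geometry,
    mesoderm_mask,
)


@pytest.fixture(scope="session")
def gparams():
    return GeometryParams()


@pytest.fixture(scope="session")
def geom(gparams):
    return build_initial_geometry(gparams)


@pytest.fixture(scope="session")
def ann(gparams):
    return mesoderm_mask(gparams.n_cells)


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
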