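import numpy as np
import pytest

import discflux as dx


@pytest.fixture(scope="session")
def healthy():
    return dx.load_parameter_set("healthy")


@pytest.fixture(scope="session")
def degenerated():
    return dx.load_parameter_set("degenerated")


@pytest.fixture(scope="session")
def disc_mesh():
    return dx.build_disc_mesh(dx.DiscGeometrySpec(resolution=1))


@pytest.fixture(scope="session")
def column():
    return dx.build_column_mesh(1.0, 20, region="NP")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)
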