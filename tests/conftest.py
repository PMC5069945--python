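import numpy as np
import pytest

from bivshape.synthetic import ModeBasis, make_template_biventricle


@pytest.fixture(scope="session")
def template():
    """Default-resolution template shared across tests."""
    return make_template_biventricle()


@pytest.fixture(scope="session")
def small_template():
    """Coarse template for tests where geometry detail is irrelevant."""
    return make_template_biventricle(12, 8)


@pytest.fixture(scope="session")
def basis(template):
    return ModeBasis(template)


@pytest.fixture(scope="session")
def small_basis(small_template):
    return ModeBasis(small_template)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
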