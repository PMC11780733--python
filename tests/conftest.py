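import numpy as np
import pytest

from puckerfit.synthetic import FiberSpec, build_fiber_duplex


@pytest.fixture(scope="session")
def b_duplex():
    """Idealized B-form 12-mer duplex with its planted ground truth."""
    return build_fiber_duplex(FiberSpec(form="B", sequence="CGCGAATTCGCG"))


@pytest.fixture(scope="session")
def a_duplex():
    """Idealized A-form 12-mer duplex with its planted ground truth."""
    return build_fiber_duplex(FiberSpec(form="A", sequence="CGCGAATTCGCG"))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
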