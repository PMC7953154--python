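import numpy as np
import pytest

from atriflow import synthetic


@pytest.fixture(scope="session")
def default_case():
    """One shared default synthetic case (subject-1-like targets)."""
    return synthetic.generate_case(synthetic.AnatomyParams())


@pytest.fixture(scope="session")
def small_case():
    """Coarser-mesh case for solver-coupled tests."""
    return synthetic.generate_case(
        synthetic.AnatomyParams(triangle_budget=1280))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
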