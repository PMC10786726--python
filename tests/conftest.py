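import pytest

from apobectools.io import load_bundled_signatures
from apobectools.simulate import simulate_reference


@pytest.fixture(scope="session")
def sigs():
    return load_bundled_signatures()


@pytest.fixture(scope="session")
def ref5k():
    return simulate_reference(5_000, 0.5, seed=11)


@pytest.fixture(scope="session")
def ref50k():
    return simulate_reference(50_000, 0.5, seed=11)
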