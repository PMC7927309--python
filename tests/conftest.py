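import numpy as np
import pytest

from tractnoddi.scheme import two_shell_scheme
from tractnoddi.synthetic import BundleSpec, default_templates, generate_bundle


@pytest.fixture(scope="session")
def scheme():
    """The default two-shell protocol (60@b3000 + 35@b711 + 11@b0)."""
    return two_shell_scheme()


@pytest.fixture(scope="session")
def templates():
    return default_templates()


@pytest.fixture(scope="session")
def bundle():
    """A 20-streamline left arcuate-like bundle, fixed seed."""
    return generate_bundle(BundleSpec("AF", "left", n_streamlines=20, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
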