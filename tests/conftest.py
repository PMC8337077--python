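import numpy as np
import pytest

import mitogerm as mg


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def test_cfg():
    """Desk-scale scenario preserving the human structural ratios."""
    return mg.make_fixture("test")
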