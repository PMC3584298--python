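import numpy as np
import pytest

import memchain as mc


@pytest.fixture
def demo_params():
    """Two-store chain used throughout the partial-lesion illustrations."""
    return mc.two_store(2.0, 0.3, 0.1, 0.0)


@pytest.fixture
def cho_params():
    """Published two-store fit to a mouse spatial-discrimination study."""
    return mc.two_store(1.50, 0.103, 0.00325, 0.0)


@pytest.fixture
def full_lesion():
    return mc.pathology_profile("korsakoff", lam=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
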