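import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def toy_haploid():
    """The 2-locus, 2-allele landscape w = (0.4, 0.6, 0.8, 1.0)."""
    from mixsim import HaploidLandscape

    return HaploidLandscape(2, 2, np.array([[0.4, 0.6], [0.8, 1.0]]))
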