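import numpy as np
import pytest

from phagelink import datasets, make_amplicon_reference


@pytest.fixture(scope="session")
def printed_measurements():
    """The published equimolar co-expression titer set."""
    return datasets.coexpression_equimolar()


@pytest.fixture(scope="session")
def amplicon_ref():
    """Synthetic 516-bp tail-fiber amplicon with planted landmark codons."""
    return make_amplicon_reference(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
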