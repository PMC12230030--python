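import numpy as np
import pytest

from ccmicro import simulate
from ccmicro.io import AbundanceTable


@pytest.fixture(scope="session")
def ccy_dataset():
    """One seeded draw of the 28-sample cropping-year fixture."""
    return simulate.simulate_ccy_dataset(1)


@pytest.fixture()
def tiny_table():
    """3 taxa x 2 samples with counts 1..6."""
    return AbundanceTable(
        taxon_ids=["t1", "t2", "t3"],
        sample_ids=["s1", "s2"],
        values=np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]),
    )
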