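import numpy as np
import pytest

from lethalmap.synthetic_data import SimConfig


@pytest.fixture
def small_config():
    """A fast, small screen used where scale does not matter."""
    return SimConfig(
        chromosome_length=1_000_000,
        n_flies=40,
        gene_catalog_size=100,
        n_deficiencies=12,
        deficiency_size_range=(40_000, 90_000),
        seed=13,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
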