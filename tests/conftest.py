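import numpy as np
import pytest

from delbench.library import enumerate_library
from delbench.synthetic import SynthConfig, synth_library


@pytest.fixture(scope="session")
def toy_defn():
    """4 x 3 x 2 chain library with valid assemblable fragments."""
    cfg = SynthConfig(cardinalities=(4, 3, 2))
    defn, _ = synth_library(cfg, with_smiles=False)
    return defn


@pytest.fixture(scope="session")
def toy_records(toy_defn):
    return list(enumerate_library(toy_defn, with_smiles=True))


@pytest.fixture(scope="session")
def toy_bb(toy_records):
    return np.asarray([r.bb_indices for r in toy_records], dtype=np.int64)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
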