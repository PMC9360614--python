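import numpy as np
import pytest

from delscreen.chem_enum import (
    FingerprintConfig,
    default_templates,
    enumerate_trisynthons,
    fingerprint_matrix,
)
from delscreen.synthetic_del import generate_building_blocks


@pytest.fixture(scope="session")
def tiny_library():
    """64 trisynthons (4 blocks per cycle) with their products."""
    blocks = generate_building_blocks(4)
    return enumerate_trisynthons(blocks, default_templates())


@pytest.fixture(scope="session")
def tiny_fp_config():
    return FingerprintConfig(n_bits=256, radius=2)


@pytest.fixture(scope="session")
def tiny_fingerprints(tiny_library, tiny_fp_config):
    X = fingerprint_matrix(
        (t.product_smiles for t in tiny_library), tiny_fp_config
    )
    return {t.compound_id: X[i] for i, t in enumerate(tiny_library)}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
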