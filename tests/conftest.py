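import numpy as np
import pytest

from mol2mat import SyntheticConfig, generate, generate_smiles_fixture


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def separable_config():
    """Small, cleanly separable 3-class fingerprint dataset."""
    return SyntheticConfig(
        n_classes=3, per_class=30, length=144, signature_size=16,
        p_signature=0.9, p_background=0.02, p_cross=0.05, seed=11,
    )


@pytest.fixture(scope="session")
def separable_data(separable_config):
    return generate(separable_config)


@pytest.fixture(scope="session")
def smiles_molecules():
    return generate_smiles_fixture(n_per_family=4, seed=3)
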