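import numpy as np
import pytest

from hidti.synthetic import SynthConfig, generate_bundle


@pytest.fixture(scope="session")
def tiny_cfg() -> SynthConfig:
    """A miniature bundle configuration for fast structural tests."""
    return SynthConfig(
        n_drugs=30,
        n_proteins=40,
        n_side_effects=15,
        n_diseases=20,
        latent_dim=4,
        drug_embedding_dim=8,
        protein_embedding_dim=6,
        seed=3,
    )


@pytest.fixture(scope="session")
def tiny_bundle(tiny_cfg):
    bundle, truth = generate_bundle(tiny_cfg)
    return bundle, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
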