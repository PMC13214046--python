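import numpy as np
import pytest

from coevolm.backbone import BackboneConfig
from coevolm.simulate import CorpusConfig, simulate_corpus


@pytest.fixture(scope="session")
def tiny_corpus():
    """Small planted corpus shared by fast unit tests."""
    cfg = CorpusConfig(n_species=30, n_ogs=40, n_levels=3, embedding_dim=16,
                       n_planted_pairs=6, seed=7)
    return simulate_corpus(cfg)


@pytest.fixture(scope="session")
def tiny_backbone_config():
    return BackboneConfig(n_layers=2, n_heads_per_layer=2, model_dim=16,
                          feedforward_dim=32, input_dim=16, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
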