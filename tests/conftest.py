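import numpy as np
import pytest

from eeggnn.graphs import GraphConfig, build_graphs
from eeggnn.model import CrossModalGraphClassifier, ModelConfig
from eeggnn.preprocess import DEFAULT_CHANNELS, zscore_epochs
from eeggnn.synth import SynthConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic corpus shared by model/train/explain tests."""
    cfg = SynthConfig(n_patients=4, epochs_per_patient=6, spasm_fraction=0.34,
                      event_snr=3.0, seed=7)
    es, truth = generate_dataset(cfg)
    return es, truth


@pytest.fixture(scope="session")
def small_graphs(small_dataset):
    es, _ = small_dataset
    esz = zscore_epochs(es)
    temporal, spectral = build_graphs(esz, GraphConfig())
    return esz, temporal, spectral


@pytest.fixture(scope="session")
def tiny_model():
    """A small-width classifier over the default 16-channel montage."""
    cfg = ModelConfig(hidden_width=16, n_heads=4, edge_mlp_hidden=8,
                      classifier_hidden=16, conv_channels=4)
    return CrossModalGraphClassifier(cfg, seed=3)


@pytest.fixture
def channel_names():
    return list(DEFAULT_CHANNELS)
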