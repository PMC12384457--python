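import numpy as np
import pytest

from gahtnet.gate import GateConfig
from gahtnet.hadte import HadteConfig
from gahtnet.model import ModelConfig
from gahtnet.montage import build_spatial_graph, load_builtin_montage


@pytest.fixture(scope="session")
def graph_2b():
    return build_spatial_graph(load_builtin_montage("2b"), K=3)


@pytest.fixture(scope="session")
def graph_2a():
    return build_spatial_graph(load_builtin_montage("2a"), K=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_model_config():
    """A 2-class, 3-electrode config on short (250-sample) epochs.

    Short epochs keep unit tests fast while exercising every stage: with
    pool sizes 8 and 7 the encoder still emits a multi-step sequence.
    """
    return ModelConfig(
        n_classes=2,
        n_electrodes=3,
        input_samples=250,
        gate=GateConfig(),
        hadte=HadteConfig(),
    )


def random_symmetric_adjacency(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random undirected graph with unit diagonal (valid adjacency input)."""
    upper = rng.random((n, n)) < 0.4
    A = np.triu(upper, 1)
    A = (A | A.T).astype(float)
    np.fill_diagonal(A, 1.0)
    return A
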