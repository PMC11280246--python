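import numpy as np
import pytest

from zdetect import DEFAULT_PAYOFFS, default_corpus, table1_history


@pytest.fixture(scope="session")
def payoffs():
    return DEFAULT_PAYOFFS


@pytest.fixture(scope="session")
def corpus():
    return default_corpus()


@pytest.fixture(scope="session")
def example_history():
    """The bundled 20-turn extortioner-vs-Alternator match."""
    return table1_history()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240726)


def random_mixed_vectors(rng, k, low=0.05, high=0.95):
    """Fully-mixed memory-one vectors, bounded away from 0/1 for ergodicity."""
    return low + (high - low) * rng.random((k, 4))
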