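import numpy as np
import pytest

from chordlearn import task_design as td


@pytest.fixture(scope="session")
def chord_set():
    return td.enumerate_chords()


@pytest.fixture(scope="session")
def sequence_pool(chord_set):
    """All valid 5-chord sequences over the 13-chord set."""
    return td.generate_sequences(chord_set)


@pytest.fixture(scope="session")
def configuration(sequence_pool):
    return td.partition_configurations(sequence_pool, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
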