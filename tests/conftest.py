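import numpy as np
import pytest

from trialterm.synthetic import SyntheticConfig, generate_records, generate_term_corpus


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(n_records=300, seed=11)


@pytest.fixture(scope="session")
def small_registry(small_config):
    """300 synthetic records with ground truth (shared, read-only)."""
    records, labels, truth = generate_records(small_config)
    return records, labels, truth


@pytest.fixture(scope="session")
def small_corpus(small_config):
    rows, planted = generate_term_corpus(small_config)
    return rows, planted


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
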