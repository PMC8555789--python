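import numpy as np
import pytest

from psmembed import SimulationConfig, Vocabulary, make_dataset


@pytest.fixture(scope="session")
def vocab():
    return Vocabulary.default()


@pytest.fixture(scope="session")
def small_dataset():
    """16 peptides x 2 spectra with generator defaults; session-cached."""
    cfg = SimulationConfig(n_peptides=16, spectra_per_peptide=2, seed=7)
    pairs, manifest = make_dataset(cfg)
    return pairs, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_unit_rows(rng, n, d):
    x = rng.normal(size=(n, d))
    return x / np.linalg.norm(x, axis=1, keepdims=True)
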