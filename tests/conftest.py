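import numpy as np
import pytest

from turnkit.simulate import (
    SyntheticCorpusSpec,
    make_helix_chain,
    make_turn_peptide,
    sample_crf_corpus,
)


@pytest.fixture(scope="session")
def helix20():
    return make_helix_chain(20)


@pytest.fixture(scope="session")
def beta_peptide():
    return make_turn_peptide("beta_I", 4)


@pytest.fixture(scope="session")
def gamma_peptide():
    return make_turn_peptide("gamma", 3)


@pytest.fixture(scope="session")
def small_corpus():
    """Small labelled corpus for CRF unit tests (not the CV benchmark)."""
    spec = SyntheticCorpusSpec(n_sequences=12, length_low=20, length_high=30,
                               seed=11)
    return sample_crf_corpus(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
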