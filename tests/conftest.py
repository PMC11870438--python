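import numpy as np
import pytest

from seq2cov.synthetic import SyntheticSpec, generate_corpus


@pytest.fixture(scope="session")
def tiny_spec():
    """A small corpus spec: 8 windows of 2,048 bp, 8 tracks."""
    return SyntheticSpec(n_windows=8, window_len=2048, mean_instances=3.0,
                         edge_margin_bins=8, n_effect_variants=6,
                         n_null_variants=6, seed=5)


@pytest.fixture(scope="session")
def tiny_corpus(tiny_spec):
    return generate_corpus(tiny_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
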